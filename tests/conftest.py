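import pytest

from escirc.locus_model import build_locus, enumerate_junctions
from escirc.synthetic_data import Cell, PopulationTruth, RecombinationEvent, SimulationConfig


def toy_config(seed=1, n_v=3, n_j=2, kde=True, **kwargs):
    segments = [
        {"name": f"V{i}", "kind": "V", "spacer_class": 12} for i in range(1, n_v + 1)
    ]
    segments += [
        {"name": f"J{i}", "kind": "J", "spacer_class": 23} for i in range(1, n_j + 1)
    ]
    if kde:
        segments.append({"name": "C", "kind": "constant"})
        segments.append({"name": "KDE", "kind": "KDE", "spacer_class": 23})
    cfg = {"seed": seed, "name": "toyIGK", "segments": segments}
    cfg.update(kwargs)
    return cfg


@pytest.fixture(scope="session")
def locus():
    return build_locus(toy_config())


@pytest.fixture(scope="session")
def db(locus):
    return enumerate_junctions(locus, flank_len=60)


@pytest.fixture(scope="session")
def wide_locus():
    # junctions separated by multiples of the default 1 kb merge distance
    return build_locus(toy_config(seed=9, n_v=5, n_j=1, kde=False, gap_after=2500))


@pytest.fixture(scope="session")
def wide_db(wide_locus):
    return enumerate_junctions(wide_locus, flank_len=60)


def manual_truth(db, copies_by_signal_id, divisions=0, seed=123, **cfg_kwargs):
    """One-cell population carrying the given SJ copy numbers (test helper)."""
    events = []
    for sid in copies_by_signal_id:
        e = db.get(sid)
        events.append(
            RecombinationEvent(
                signal_id=sid,
                coding_id=sid.replace("|signal", "|coding"),
                v_name=e.partner_b,
                j_name=e.partner_a,
                insert="",
                allele=0,
                generation=0,
            )
        )
    cfg = SimulationConfig(seed=seed, **cfg_kwargs)
    cell = Cell(0, 0, events, dict(copies_by_signal_id))
    return PopulationTruth([cell], divisions, cfg)
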