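"""Strategy catalog: golden traces, classifiers, generic families, loader."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipdlab.game import Action, C, D, DEFAULT_PAYOFFS, MatchConfig, MatchContext, play_match
from ipdlab.strategies import (
    FSM,
    Lookup,
    MemoryOne,
    MetaMajority,
    MetaWinner,
    Cooperator,
    Defector,
    GenerousTitForTat,
    TitForTat,
    build_catalog,
    classify,
    generous_probability,
    load_strategies,
    zd_extort_2,
)
from conftest import GOLDEN_TRACES


def _trace(registry, name, opponent, turns=10, seed=0):
    res, _ = play_match(
        registry[name].factory(),
        registry[opponent].factory(),
        MatchConfig(turns=turns, seed=seed),
    )
    return "".join(a.name for a in res.focal_actions())


@pytest.mark.parametrize("name,opponent,expected", GOLDEN_TRACES)
def test_golden_traces(registry, name, opponent, expected):
    """Every deterministic catalog strategy reproduces its hand-derived trace."""
    assert _trace(registry, name, opponent) == expected


def test_catalog_has_expected_classifiers(registry):
    tft = registry["Tit For Tat"]
    assert not tft.stochastic and tft.memory_size == 1
    assert not tft.makes_use_of_game and not tft.makes_use_of_length
    assert registry["ZD-Extort-2"].stochastic
    assert registry["ZD-Extort-2"].memory_size == 1
    assert registry["BackStabber"].makes_use_of_length
    assert registry["Grudger"].memory_size == math.inf
    assert registry["Random"].stochastic


def test_classify_by_name_and_unknown_error(registry):
    record = classify("Grudger", registry)
    assert record["memory_size"] == math.inf
    with pytest.raises(KeyError):
        classify("No Such Strategy", registry)


def test_duplicate_registration_is_an_error():
    with pytest.raises(ValueError, match="duplicate"):
        build_catalog([Cooperator, Cooperator])


def test_generous_tft_probability_is_one_third_at_defaults():
    assert generous_probability(DEFAULT_PAYOFFS) == pytest.approx(1 / 3)
    # Empirical: after an opponent defection GTFT forgives ~1/3 of the time.
    gtft = GenerousTitForTat()
    ctx = MatchContext(payoffs=DEFAULT_PAYOFFS, turns=None)
    rng = np.random.default_rng(0)
    n = 3000
    forgiven = sum(
        gtft.next_action([C], [D], ctx, rng) == C for _ in range(n)
    )
    se = math.sqrt((1 / 3) * (2 / 3) / n)
    assert abs(forgiven / n - 1 / 3) < 3 * se


def test_memory_one_vector_1010_is_tit_for_tat():
    """A (1,0,1,0) memory-one rule matches TFT on arbitrary histories."""
    rng_hist = np.random.default_rng(1)
    m1 = MemoryOne((1, 0, 1, 0), initial=C)
    tft = TitForTat()
    ctx = MatchContext(payoffs=DEFAULT_PAYOFFS, turns=None)
    rng = np.random.default_rng(2)
    for _ in range(200):
        length = int(rng_hist.integers(0, 20))
        own = [Action(int(a)) for a in rng_hist.integers(0, 2, size=length)]
        opp = [Action(int(a)) for a in rng_hist.integers(0, 2, size=length)]
        assert m1.next_action(own, opp, ctx, rng) == tft.next_action(own, opp, ctx, rng)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    vector=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    own=st.integers(0, 1),
    opp=st.integers(0, 1),
)
def test_memory_one_always_returns_a_valid_action(vector, own, opp):
    m1 = MemoryOne(vector)
    ctx = MatchContext(payoffs=DEFAULT_PAYOFFS, turns=None)
    rng = np.random.default_rng(0)
    action = m1.next_action([Action(own)], [Action(opp)], ctx, rng)
    assert action in (C, D)


def test_memory_one_invalid_vector_raises():
    with pytest.raises(ValueError):
        MemoryOne((1.2, 0, 0, 0))
    with pytest.raises(ValueError):
        MemoryOne((0.5, 0.5, 0.5))


def test_reset_gives_identical_replay(registry):
    """Two matches from the same factories and seed are bit-identical."""
    for name in ("Random", "ZD-Extort-2", "Gradual", "Meta Winner"):
        cfg = MatchConfig(turns=30, noise=0.05, seed=11)
        first = play_match(
            registry[name].factory(), registry["Tit For Tat"].factory(), cfg
        )
        second = play_match(
            registry[name].factory(), registry["Tit For Tat"].factory(), cfg
        )
        assert first[0].rounds == second[0].rounds


def test_meta_majority_of_identical_members_equals_member(registry):
    meta = MetaMajority([TitForTat, TitForTat, TitForTat], name="3xTFT")
    res_meta, _ = play_match(
        meta, registry["Alternator"].factory(), MatchConfig(turns=10, seed=0)
    )
    res_tft, _ = play_match(
        TitForTat(), registry["Alternator"].factory(), MatchConfig(turns=10, seed=0)
    )
    assert res_meta.rounds == res_tft.rounds


def test_meta_winner_tracks_best_hypothetical_scorer(registry):
    # Against a pure defector the defecting team member accrues the larger
    # hypothetical score, so the ensemble switches to defection.
    meta = MetaWinner([Cooperator, Defector], name="CW")
    res, _ = play_match(meta, registry["Defector"].factory(), MatchConfig(turns=10, seed=0))
    actions = res.focal_actions()
    assert actions[0] == C  # tie at the start goes to the earliest member
    assert all(a == D for a in actions[3:])


def test_fsm_and_lookup_express_tit_for_tat(registry):
    fsm = FSM(
        transitions={
            (0, C): (0, C),
            (0, D): (1, D),
            (1, C): (0, C),
            (1, D): (1, D),
        },
        initial_state=0,
        initial_action=C,
        name="FSM-TFT",
    )
    table = {
        ((C,), (C,)): C,
        ((C,), (D,)): D,
        ((D,), (C,)): C,
        ((D,), (D,)): D,
    }
    lookup = Lookup(table, memory=1, openings=[C], name="Lookup-TFT")
    for strat in (fsm, lookup):
        res, _ = play_match(
            strat, registry["Alternator"].factory(), MatchConfig(turns=10, seed=0)
        )
        assert "".join(a.name for a in res.focal_actions()) == "CCDCDCDCDC"


def test_fsm_validation():
    with pytest.raises(ValueError, match="missing"):
        FSM({(0, C): (0, C)}, initial_state=0)
    with pytest.raises(ValueError, match="initial state"):
        FSM(
            {(0, C): (0, C), (0, D): (0, D)},
            initial_state=99,
        )


def test_lookup_validation():
    with pytest.raises(ValueError, match="cover"):
        Lookup({((C,), (C,)): C}, memory=1, openings=[C])
    full = {
        ((a,), (b,)): C for a in (C, D) for b in (C, D)
    }
    with pytest.raises(ValueError, match="openings"):
        Lookup(full, memory=1, openings=[C, C])


def test_loader_round_trip_and_validation(tmp_path):
    doc = {
        "strategies": [
            {"type": "memory_one", "name": "TFT-vec", "vector": [1, 0, 1, 0]},
            {
                "type": "fsm",
                "name": "Grim-FSM",
                "initial_state": 0,
                "initial_action": "C",
                "transitions": [
                    [0, "C", 0, "C"],
                    [0, "D", 1, "D"],
                    [1, "C", 1, "D"],
                    [1, "D", 1, "D"],
                ],
            },
            {
                "type": "lookup",
                "name": "L-TFT",
                "memory": 1,
                "openings": ["C"],
                "table": {"C|C": "C", "C|D": "D", "D|C": "C", "D|D": "D"},
            },
        ]
    }
    specs = load_strategies(doc)
    assert [s.name for s in specs] == ["TFT-vec", "Grim-FSM", "L-TFT"]
    # Grim-FSM behaves like Grudger.
    res, _ = play_match(specs[1].factory(), Defector(), MatchConfig(turns=5, seed=0))
    assert "".join(a.name for a in res.focal_actions()) == "CDDDD"

    # YAML file path round trip.
    import yaml

    path = tmp_path / "strategies.yaml"
    path.write_text(yaml.safe_dump(doc))
    specs2 = load_strategies(str(path))
    assert [s.name for s in specs2] == [s.name for s in specs]

    with pytest.raises(ValueError, match="unknown strategy type"):
        load_strategies({"strategies": [{"type": "neural"}]})
    with pytest.raises(ValueError, match="duplicate"):
        load_strategies(
            {
                "strategies": [
                    {"type": "memory_one", "name": "X", "vector": [1, 0, 1, 0]},
                    {"type": "memory_one", "name": "X", "vector": [0, 0, 0, 0]},
                ]
            }
        )


def test_zd_extort_2_vector(registry):
    proto = zd_extort_2()
    assert proto.vector == pytest.approx((8 / 9, 1 / 2, 1 / 3, 0.0))
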