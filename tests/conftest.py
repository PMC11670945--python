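"""Shared fixtures: the strategy catalog and hand-derived golden traces."""

import pytest

from ipdlab.strategies import catalog

# Hand-derived 10-round action traces for every deterministic catalog
# strategy against fixed-pattern opponents (noise-free, n=10 known).
# Each entry: (strategy name, opponent name, focal action string).
GOLDEN_TRACES = [
    ("Cooperator", "Cooperator", "CCCCCCCCCC"),
    ("Cooperator", "Defector", "CCCCCCCCCC"),
    ("Cooperator", "Alternator", "CCCCCCCCCC"),
    ("Defector", "Cooperator", "DDDDDDDDDD"),
    ("Defector", "Defector", "DDDDDDDDDD"),
    ("Defector", "Alternator", "DDDDDDDDDD"),
    ("Alternator", "Cooperator", "CDCDCDCDCD"),
    ("Alternator", "Defector", "CDCDCDCDCD"),
    ("Alternator", "Alternator", "CDCDCDCDCD"),
    ("Tit For Tat", "Cooperator", "CCCCCCCCCC"),
    ("Tit For Tat", "Defector", "CDDDDDDDDD"),
    ("Tit For Tat", "Alternator", "CCDCDCDCDC"),
    ("Suspicious Tit For Tat", "Cooperator", "DCCCCCCCCC"),
    ("Suspicious Tit For Tat", "Defector", "DDDDDDDDDD"),
    ("Suspicious Tit For Tat", "Alternator", "DCDCDCDCDC"),
    ("Tit For 2 Tats", "Cooperator", "CCCCCCCCCC"),
    ("Tit For 2 Tats", "Defector", "CCDDDDDDDD"),
    ("Tit For 2 Tats", "Alternator", "CCCCCCCCCC"),
    ("Two Tits For Tat", "Cooperator", "CCCCCCCCCC"),
    ("Two Tits For Tat", "Defector", "CDDDDDDDDD"),
    ("Two Tits For Tat", "Alternator", "CCDDDDDDDD"),
    ("Grudger", "Cooperator", "CCCCCCCCCC"),
    ("Grudger", "Defector", "CDDDDDDDDD"),
    ("Grudger", "Alternator", "CCDDDDDDDD"),
    ("Spiteful Tit For Tat", "Cooperator", "CCCCCCCCCC"),
    ("Spiteful Tit For Tat", "Defector", "CDDDDDDDDD"),
    ("Spiteful Tit For Tat", "Alternator", "CCDCDCDCDC"),
    ("Fool Me Once", "Cooperator", "CCCCCCCCCC"),
    ("Fool Me Once", "Defector", "CCDDDDDDDD"),
    ("Fool Me Once", "Alternator", "CCCCDDDDDD"),
    ("Pavlov", "Cooperator", "CCCCCCCCCC"),
    ("Pavlov", "Defector", "CDCDCDCDCD"),
    ("Pavlov", "Alternator", "CCDDCCDDCC"),
    ("Gradual", "Cooperator", "CCCCCCCCCC"),
    ("Gradual", "Defector", "CDCCDDDDCC"),
    ("Gradual", "Alternator", "CCDCCCDDDC"),
    ("Adaptive Tit For Tat", "Cooperator", "CCCCCCCCCC"),
    ("Adaptive Tit For Tat", "Defector", "CDDDDDDDDD"),
    ("Adaptive Tit For Tat", "Alternator", "CCDCDCDCDC"),
    ("Omega TFT", "Cooperator", "CCCCCCCCCC"),
    ("Omega TFT", "Defector", "CDDDDDDDDD"),
    ("Omega TFT", "Alternator", "CCDCDCDDDD"),
    ("Prober", "Cooperator", "DCCDDDDDDD"),
    ("Prober", "Defector", "DCCDDDDDDD"),
    ("Prober", "Alternator", "DCCCDCDCDC"),
    ("BackStabber", "Cooperator", "CCCCCCCCDD"),
    ("BackStabber", "Defector", "CCCCDDDDDD"),
    ("BackStabber", "Alternator", "CCCCCCCCDD"),
]


@pytest.fixture(scope="session")
def registry():
    return catalog()


@pytest.fixture(scope="session")
def golden_traces():
    return GOLDEN_TRACES
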