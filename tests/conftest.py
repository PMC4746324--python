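"""Shared fixtures: tiny hand-written networks and generated bundles."""

from fractions import Fraction as F

import numpy as np
import pytest

from fluxsense.netcore import MetabolicNetwork, Metabolite, Reaction


@pytest.fixture
def chain_network():
    """EX_A (ub 10) -> A -> B -> biomass drain: a single-bottleneck chain."""
    mets = [Metabolite("A[c]", "c"), Metabolite("B[c]", "c")]
    rxns = [
        Reaction("EX_A", {"A[c]": F(1)}, lb=0, ub=10),
        Reaction("R_AB", {"A[c]": F(-1), "B[c]": F(1)}, lb=0, ub=1000),
        Reaction("BIO", {"B[c]": F(-1)}, lb=0, ub=1000),
    ]
    return MetabolicNetwork(["c"], mets, rxns, "BIO")


@pytest.fixture
def fixture_4x5():
    """4-metabolite, 5-reaction network with its hand-transcribed S matrix."""
    mets = [Metabolite(f"{x}[c]", "c") for x in "ABCD"]
    rxns = [
        Reaction("r1", {"A[c]": F(-1), "B[c]": F(1)}),
        Reaction("r2", {"B[c]": F(-2), "C[c]": F(1)}),
        Reaction("r3", {"A[c]": F(-1), "C[c]": F(-1), "D[c]": F(1)}),
        Reaction("r4", {"A[c]": F(1)}, lb=0, ub=10),
        Reaction("r5", {"D[c]": F(-1)}),
    ]
    net = MetabolicNetwork(["c"], mets, rxns, "r5")
    # rows A,B,C,D; columns r1..r5 (both lexicographic)
    expected = np.array(
        [
            [-1, 0, -1, 1, 0],
            [1, -2, 0, 0, 0],
            [0, 1, -1, 0, 0],
            [0, 0, 1, 0, -1],
        ],
        dtype=float,
    )
    return net, expected


@pytest.fixture
def branched_network():
    """6-reaction branched network: two routes with different capacities."""
    mets = [Metabolite(m, "c") for m in ("A[c]", "B[c]", "C[c]")]
    rxns = [
        Reaction("EX_A", {"A[c]": F(1)}, lb=0, ub=8),
        Reaction("fast", {"A[c]": F(-1), "B[c]": F(1)}, lb=0, ub=5),
        Reaction("slow", {"A[c]": F(-2), "B[c]": F(1)}, lb=0, ub=4),
        Reaction("join", {"B[c]": F(-1), "C[c]": F(1)}, lb=0, ub=1000),
        Reaction("leak", {"B[c]": F(-1)}, lb=0, ub=1),
        Reaction("BIO", {"C[c]": F(-1)}, lb=0, ub=1000),
    ]
    return MetabolicNetwork(["c"], mets, rxns, "BIO")
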