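"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming implementations:
the Viterbi oracle enumerates every local state path explicitly, the t-test
oracle integrates the t density numerically, and the pathway oracle
enumerates presence/absence subsets.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from reservescan.alphabet import N_RESIDUES, UNIFORM_BACKGROUND
from reservescan.model_factory import ProfileModel


def random_profile(rng: np.random.Generator, m: int) -> ProfileModel:
    """A small random (but valid) profile model for oracle comparisons."""
    match = rng.dirichlet(np.full(N_RESIDUES, 0.5), size=m)
    t_match = rng.dirichlet((8.0, 1.0, 1.0), size=m)
    t_insert = rng.dirichlet((3.0, 1.0), size=m)
    t_delete = rng.dirichlet((3.0, 1.0), size=m)
    t_match[m - 1] = [1.0, 0.0, 0.0]
    t_insert[m - 1] = [1.0, 0.0]
    t_delete[m - 1] = [1.0, 0.0]
    return ProfileModel(
        model_id=f"random_m{m}",
        source_enzyme="",
        match_emissions=match,
        insert_emissions=UNIFORM_BACKGROUND.copy(),
        t_match=t_match,
        t_insert=t_insert,
        t_delete=t_delete,
        background=UNIFORM_BACKGROUND.copy(),
        query_length_aa=m,
    )


def enumerate_viterbi(model: ProfileModel, seq: np.ndarray) -> float:
    """Best local alignment score by exhaustive enumeration of state paths.

    Paths start and end on a match state; inserts emit background (log-odds
    0); begin may enter any match state at cost -log2(m).  Feasible for
    m <= 6 and len(seq) <= 12.
    """
    m = model.match_length
    L = len(seq)
    with np.errstate(divide="ignore"):
        lm = np.log2(model.match_emissions / model.background)
        lMM = np.log2(model.t_match[:, 0])
        lMI = np.log2(model.t_match[:, 1])
        lMD = np.log2(model.t_match[:, 2])
        lIM = np.log2(model.t_insert[:, 0])
        lII = np.log2(model.t_insert[:, 1])
        lDM = np.log2(model.t_delete[:, 0])
        lDD = np.log2(model.t_delete[:, 1])
    entry = -math.log2(m)

    def em(t: int, k: int) -> float:
        r = seq[t]
        return 0.0 if r >= N_RESIDUES else float(lm[k, r])

    best = [-math.inf]

    def walk(state: str, k: int, t: int, score: float) -> None:
        # (state, k, t): just arrived in `state` with residue index t consumed
        if state == "M":
            if score > best[0]:
                best[0] = score
            if k + 1 < m and t + 1 < L:
                walk("M", k + 1, t + 1, score + lMM[k] + em(t + 1, k + 1))
            if t + 1 < L:
                walk("I", k, t + 1, score + lMI[k])
            if k + 1 < m:
                walk("D", k + 1, t, score + lMD[k])
        elif state == "I":
            if t + 1 < L:
                walk("I", k, t + 1, score + lII[k])
            if k + 1 < m and t + 1 < L:
                walk("M", k + 1, t + 1, score + lIM[k] + em(t + 1, k + 1))
        else:  # D
            if k + 1 < m:
                walk("D", k + 1, t, score + lDD[k])
            if k + 1 < m and t + 1 < L:
                walk("M", k + 1, t + 1, score + lDM[k] + em(t + 1, k + 1))

    for t0 in range(L):
        for k0 in range(m):
            walk("M", k0, t0, entry + em(t0, k0))
    return best[0]


def t_pvalue_by_integration(t_stat: float, df: float) -> float:
    """Two-tailed p value by numerical integration of the t density."""
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def density(x: float) -> float:
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(density, abs(t_stat), np.inf)
    return min(1.0, 2.0 * tail)


def pathway_truth_table(required: frozenset[str], all_enzymes: list[str]):
    """Enumerate every presence/absence pattern over ``all_enzymes`` and the
    expected pathway call (all required present)."""
    import itertools

    for pattern in itertools.product([0, 1], repeat=len(all_enzymes)):
        present = {e for e, bit in zip(all_enzymes, pattern) if bit}
        yield dict(zip(all_enzymes, pattern)), required <= present
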