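"""KING-robust kinship estimation and greedy relatedness pruning.

The kinship coefficient for a pair (i, j) is estimated from genotype counts
over sites co-called in both samples:

    phi = (N_AaAa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))

where N_AaAa counts sites at which both samples are heterozygous, N_AA,aa
counts opposite homozygotes, and N_Aa(i) is sample i's heterozygote count
over the co-called sites.  The estimator is robust to population structure.
Expected values: duplicates/MZ 0.5, parent-offspring and full sibs 0.25,
half sibs 0.125, first cousins 0.0625, unrelated 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ParameterError

KIN_COLUMNS = [
    "sample_i", "sample_j", "n_both_het", "n_opp_hom",
    "n_het_i", "n_het_j", "phi", "defined",
]


def king_kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs KING-robust kinship estimates.

    Returns one row per unordered sample pair with the count fields and
    ``phi``; pairs with no heterozygous co-called sites are flagged
    ``defined=False`` (phi is NaN there).
    """
    if gm.n_samples < 2:
        raise ParameterError("king_kinship needs at least two samples")
    called = gm.called()
    het = (gm.dosage == 1) & called
    hom_ref = (gm.dosage == 0) & called
    hom_alt = (gm.dosage == 2) & called

    C = called.astype(np.float64)
    H = het.astype(np.float64)
    R = hom_ref.astype(np.float64)
    A = hom_alt.astype(np.float64)

    n_both_het = H @ H.T
    n_opp = R @ A.T + A @ R.T
    het_co = H @ C.T  # het in row sample, co-called with column sample

    rows = []
    for i in range(gm.n_samples):
        for j in range(i + 1, gm.n_samples):
            hi, hj = het_co[i, j], het_co[j, i]
            denom = hi + hj
            defined = denom > 0
            phi = (n_both_het[i, j] - 2.0 * n_opp[i, j]) / denom if defined else np.nan
            rows.append(
                (gm.samples[i], gm.samples[j], int(n_both_het[i, j]),
                 int(n_opp[i, j]), int(hi), int(hj), phi, bool(defined))
            )
    return pd.DataFrame(rows, columns=KIN_COLUMNS)


def select_unrelated(
    kin: pd.DataFrame,
    cutoff: float = 0.0625,
    call_rates: dict | None = None,
) -> set[str]:
    """Greedy selection of a mutually unrelated sample set.

    Repeatedly removes the sample involved in the most pairs with
    phi >= ``cutoff`` (ties broken by lower call rate, then lexically larger
    id) until no such pair remains.  The result never contains a pair at or
    above the cutoff, and is invariant to the order of the input rows.
    """
    if kin.empty:
        return set()
    samples = sorted(set(kin["sample_i"]) | set(kin["sample_j"]))
    over = kin[(kin["phi"] >= cutoff) & kin["defined"]]
    edges = {s: set() for s in samples}
    for si, sj in zip(over["sample_i"], over["sample_j"]):
        edges[si].add(sj)
        edges[sj].add(si)

    removed: set[str] = set()
    while True:
        degree = {s: len(edges[s] - removed) for s in samples if s not in removed}
        worst = max(degree.values(), default=0)
        if worst == 0:
            break
        cands = [s for s, d in degree.items() if d == worst]
        if call_rates:
            low = min(call_rates.get(s, 1.0) for s in cands)
            cands = [s for s in cands if call_rates.get(s, 1.0) == low]
        removed.add(max(cands))  # lexically larger id goes first
    return set(samples) - removed
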