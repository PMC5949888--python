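"""Enrichment and distribution-comparison statistics for labelled peptide sets."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .encodings import AA_ORDER


def aa_enrichment(functional, nonfunctional, pseudocount: float = 0.5) -> dict[str, float]:
    """Per-residue log2 enrichment of functional over non-functional peptides.

    Frequencies are computed from pooled residue counts with a +0.5
    pseudocount so residues absent from one set stay finite.
    """
    func = list(functional)
    nonfunc = list(nonfunctional)
    if not func or not nonfunc:
        raise ValueError("both peptide sets must be non-empty")

    def freqs(peps):
        counts = {aa: pseudocount for aa in AA_ORDER}
        for p in peps:
            for aa in p:
                counts[aa] += 1
        total = sum(counts.values())
        return {aa: c / total for aa, c in counts.items()}

    f_pos, f_neg = freqs(func), freqs(nonfunc)
    return {aa: float(np.log2(f_pos[aa] / f_neg[aa])) for aa in AA_ORDER}


def motif_enrichment(
    with_pos: int, without_pos: int, with_neg: int, without_neg: int
) -> float:
    """Odds ratio of motif occurrence: (with+/without+)/(with-/without-)."""
    if min(without_pos, with_neg, without_neg) <= 0:
        raise ValueError("zero denominator in motif enrichment")
    return (with_pos / without_pos) / (with_neg / without_neg)


def compare_distributions(values_pos, values_neg) -> dict:
    """Two-sided rank-sum comparison of a feature between labelled sets.

    Mann-Whitney U with the exact null for small untied samples and the
    tie-corrected normal approximation otherwise; medians of both samples
    and their difference are reported alongside.
    """
    a = np.asarray(list(values_pos), dtype=float)
    b = np.asarray(list(values_neg), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_pos": float(np.median(a)),
        "median_neg": float(np.median(b)),
        "median_difference": float(np.median(a) - np.median(b)),
    }
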