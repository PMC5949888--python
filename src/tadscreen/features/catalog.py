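"""The encode -> view -> aggregate feature framework and the default catalog.

Every feature is computed in three steps: a numerical *encoding* turns the
peptide into numbers (a per-residue scale, a group membership indicator, or
a regular-expression pattern), a *view* selects subsequences (the full
sequence or sliding windows), and an *aggregator* (count, sum, mean, max,
presence) collapses the values to one number. The default catalog holds
exactly 146 features across eight feature sets: single amino-acid
composition (20), grouped composition (11), degenerate mini-motifs (108),
the nine-residue TAD motif (1), disorder propensity (1), helicity (2),
general properties (2: length, molecular weight) and isoelectric point (1).
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ..seqs import check_peptide
from .encodings import (
    AA_GROUPS,
    AA_ORDER,
    COARSE_GROUPS,
    DISORDER_SCALE,
    FINE_GROUPS,
    FP_HYDROPHOBICITY,
    HELIX_PROPENSITY,
    HYDROPHOBIC_SET,
    MINIMOTIF_GROUPS,
    NEGATIVE_SIDECHAINS,
    PKA_CTERM,
    PKA_NTERM,
    PKA_SIDECHAIN,
    POSITIVE_SIDECHAINS,
    load_ninetad_patterns,
)

SCALES = {
    "disorder": DISORDER_SCALE,
    "helix_propensity": HELIX_PROPENSITY,
    "fp_hydrophobicity": FP_HYDROPHOBICITY,
}

MINIMOTIF_GAP_BANDS = ((0, 2), (3, 6), (7, 10))

#: Features always retained through redundancy pruning: the properties
#: historically associated with TADs.
FORCED_KEEP_FEATURES = (
    "general_length",
    "pi",
    "comp_group_hydrophobic",
    "disorder_mean",
    "helicity_mean",
    "ninetad_presence",
)


@dataclass(frozen=True)
class FeatureDef:
    feature_id: str
    feature_set: str
    kind: str  # scale | membership | pattern | ninetad | scalar
    payload: str
    view: str = "full"  # "full" or "window:<size>"
    aggregator: str = "mean"  # count | sum | mean | max | presence

    def window_size(self) -> int | None:
        if self.view.startswith("window:"):
            size = int(self.view.split(":", 1)[1])
            if size < 1:
                raise ValueError("window size must be >= 1")
            return size
        if self.view != "full":
            raise ValueError(f"unknown view: {self.view!r}")
        return None


# ---------------------------------------------------------------------------
# basic composition operations


def aa_composition(peptide: str) -> dict[str, float]:
    """Per-residue frequencies in the fixed IVLAFWYGSPKRHDETQNCM order."""
    check_peptide(peptide)
    if not peptide:
        raise ValueError("empty peptide has no composition")
    n = len(peptide)
    return {aa: peptide.count(aa) / n for aa in AA_ORDER}


def group_composition(peptide: str) -> dict[str, float]:
    """Fractions of residues in each of the 11 (overlapping) groups."""
    check_peptide(peptide)
    if not peptide:
        raise ValueError("empty peptide has no composition")
    n = len(peptide)
    return {
        name: sum(1 for aa in peptide if aa in members) / n
        for name, members in AA_GROUPS.items()
    }


# ---------------------------------------------------------------------------
# degenerate mini-motifs


def minimotif_pattern(
    group1: str,
    group2: str,
    min_gap: int = 0,
    max_gap: int = 10,
    symmetric: bool = False,
) -> str:
    """Regex for: one group1 residue, 0-10 arbitrary residues, one group2.

    ``symmetric`` also accepts the reversed order (used for unordered group
    pairs). The pattern is wrapped in a lookahead so matches can be scanned
    at every start position (overlapping occurrences all count).
    """
    g1 = f"[{MINIMOTIF_GROUPS[group1]}]"
    g2 = f"[{MINIMOTIF_GROUPS[group2]}]"
    gap = f".{{{min_gap},{max_gap}}}"
    core = f"{g1}{gap}{g2}"
    if symmetric and group1 != group2:
        core = f"(?:{core}|{g2}{gap}{g1})"
    return f"(?=(?:{core}))"


def minimotif_feature(peptide: str, pattern: str, aggregator: str = "presence"):
    """Overlapping-start scan of a mini-motif pattern over a peptide."""
    matches = len(re.findall(pattern, peptide))
    if aggregator == "count":
        return matches
    if aggregator == "presence":
        return int(matches > 0)
    raise ValueError(f"mini-motif aggregator must be presence or count")


# ---------------------------------------------------------------------------
# nine-residue TAD motif

_NINETAD_CACHE: list[re.Pattern] | None = None


def _ninetad_patterns() -> list[re.Pattern]:
    global _NINETAD_CACHE
    if _NINETAD_CACHE is None:
        _NINETAD_CACHE = [re.compile(p) for p in load_ninetad_patterns()]
    return _NINETAD_CACHE


def nine_aa_tad(peptide: str, patterns: list[str] | None = None) -> int:
    """1 iff any of the four nine-residue TAD patterns matches."""
    pats = (
        [re.compile(p) for p in patterns]
        if patterns is not None
        else _ninetad_patterns()
    )
    return int(any(p.search(peptide) for p in pats))


# ---------------------------------------------------------------------------
# scalar physicochemical properties


def net_charge(peptide: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (terminal + side chains)."""
    pos = [PKA_NTERM] + [PKA_SIDECHAIN[aa] for aa in peptide if aa in POSITIVE_SIDECHAINS]
    neg = [PKA_CTERM] + [PKA_SIDECHAIN[aa] for aa in peptide if aa in NEGATIVE_SIDECHAINS]
    plus = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    minus = sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return plus - minus


def isoelectric_point(peptide: str, tol: float = 1e-4, max_iter: int = 100) -> float:
    """pI by bisection on the net-charge curve (monotone decreasing in pH)."""
    check_peptide(peptide)
    if not peptide:
        raise ValueError("empty peptide has no pI")
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        charge = net_charge(peptide, mid)
        if charge == 0.0 or hi - lo < 1e-8:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2
    if abs(net_charge(peptide, mid)) > tol:  # pragma: no cover - monotone curve
        raise RuntimeError(f"pI bisection did not reach |charge| < {tol}")
    return mid


def hydrophobic_fraction(peptide: str) -> float:
    if not peptide:
        raise ValueError("empty peptide")
    return sum(1 for aa in peptide if aa in HYDROPHOBIC_SET) / len(peptide)


def _normalized_mean(peptide: str, scale: dict[str, float]) -> float:
    lo, hi = min(scale.values()), max(scale.values())
    mean = sum(scale[aa] for aa in peptide) / len(peptide)
    return (mean - lo) / (hi - lo)


def disorder_proxy(peptide: str) -> float:
    """Min-max-normalized mean disorder propensity (0 ordered, 1 disordered)."""
    if not peptide:
        raise ValueError("empty peptide")
    return _normalized_mean(peptide, DISORDER_SCALE)


def helicity_proxy(peptide: str) -> float:
    """1 minus the normalized mean helix-propensity free energy."""
    if not peptide:
        raise ValueError("empty peptide")
    return 1.0 - _normalized_mean(peptide, HELIX_PROPENSITY)


def hydrophobic_moment(peptide: str, angle_deg: float = 100.0) -> float:
    """Helical hydrophobic moment per residue (Fauchere-Pliska scale)."""
    if not peptide:
        raise ValueError("empty peptide")
    angles = np.deg2rad(angle_deg) * np.arange(len(peptide))
    h = np.array([FP_HYDROPHOBICITY[aa] for aa in peptide])
    return float(np.hypot((h * np.sin(angles)).sum(), (h * np.cos(angles)).sum()) / len(peptide))


def molecular_weight(peptide: str) -> float:
    if not peptide:
        raise ValueError("empty peptide")
    return float(ProteinAnalysis(peptide).molecular_weight())


_SCALARS = {
    "length": lambda p: float(len(p)),
    "molecular_weight": molecular_weight,
    "pi": isoelectric_point,
    "hydrophobic_fraction": hydrophobic_fraction,
    "disorder": disorder_proxy,
    "helicity": helicity_proxy,
    "hydrophobic_moment": hydrophobic_moment,
}


def scalar_properties(peptide: str) -> dict[str, float]:
    """The scalar property block: length, MW, pI, hydrophobicity, disorder,
    helicity and hydrophobic moment, in documented units."""
    check_peptide(peptide)
    return {name: fn(peptide) for name, fn in _SCALARS.items()}


# ---------------------------------------------------------------------------
# generic feature computation


def _views(peptide: str, window: int | None):
    if window is None:
        return [peptide]
    if len(peptide) < window:
        return [peptide]
    return [peptide[i : i + window] for i in range(len(peptide) - window + 1)]


def _aggregate(values: list[float], aggregator: str) -> float:
    if aggregator == "count":
        return float(sum(values))
    if aggregator == "sum":
        return float(sum(values))
    if aggregator == "mean":
        return float(np.mean(values)) if values else 0.0
    if aggregator == "max":
        return float(max(values)) if values else 0.0
    if aggregator == "presence":
        return float(any(v > 0 for v in values))
    raise ValueError(f"unknown aggregator: {aggregator!r}")


def compute_feature(peptide: str, fdef: FeatureDef) -> float:
    """Encode, slice views, aggregate. Deterministic and total for any
    non-empty standard-alphabet peptide."""
    check_peptide(peptide)
    if not peptide:
        raise ValueError("empty peptide cannot be featurized")
    window = fdef.window_size()
    if fdef.kind == "scalar":
        return float(_SCALARS[fdef.payload](peptide))
    if fdef.kind == "ninetad":
        return float(nine_aa_tad(peptide))
    if fdef.kind == "pattern":
        per_view = [
            float(len(re.findall(fdef.payload, v))) for v in _views(peptide, window)
        ]
        return _aggregate(per_view, fdef.aggregator)
    if fdef.kind == "scale":
        scale = SCALES[fdef.payload]
        pooled = [scale[aa] for v in _views(peptide, window) for aa in v]
        return _aggregate(pooled, fdef.aggregator)
    if fdef.kind == "membership":
        members = set(fdef.payload)
        pooled = [
            1.0 if aa in members else 0.0
            for v in _views(peptide, window)
            for aa in v
        ]
        return _aggregate(pooled, fdef.aggregator)
    raise ValueError(f"unknown encoding kind: {fdef.kind!r}")


# ---------------------------------------------------------------------------
# the default catalog


def default_catalog_definitions() -> list[FeatureDef]:
    """Programmatic definition of the 146-feature default catalog."""
    defs: list[FeatureDef] = []
    for aa in AA_ORDER:
        defs.append(
            FeatureDef(f"comp_aa_{aa}", "aa_composition", "membership", aa)
        )
    for name in AA_GROUPS:
        defs.append(
            FeatureDef(
                f"comp_group_{name}",
                "group_composition",
                "membership",
                AA_GROUPS[name],
            )
        )
    # 18 group pairs: ordered fine x fine, unordered fine-coarse,
    # unordered coarse pairs (incl. self); 3 gap bands; 2 aggregators
    pairs: list[tuple[str, str, bool]] = []
    for g1, g2 in itertools.product(FINE_GROUPS, FINE_GROUPS):
        pairs.append((g1, g2, False))
    for g1 in FINE_GROUPS:
        for g2 in COARSE_GROUPS:
            pairs.append((g1, g2, True))
    for g1, g2 in itertools.combinations_with_replacement(COARSE_GROUPS, 2):
        pairs.append((g1, g2, True))
    for g1, g2, symmetric in pairs:
        for lo, hi in MINIMOTIF_GAP_BANDS:
            pattern = minimotif_pattern(g1, g2, lo, hi, symmetric=symmetric)
            for agg in ("presence", "count"):
                defs.append(
                    FeatureDef(
                        f"mm_{g1}_{g2}_gap{lo}_{hi}_{agg}",
                        "minimotif",
                        "pattern",
                        pattern,
                        aggregator=agg,
                    )
                )
    defs.append(FeatureDef("ninetad_presence", "ninetad", "ninetad", ""))
    defs.append(FeatureDef("disorder_mean", "disorder", "scalar", "disorder"))
    defs.append(FeatureDef("helicity_mean", "helicity", "scalar", "helicity"))
    defs.append(
        FeatureDef(
            "helicity_hydrophobic_moment", "helicity", "scalar", "hydrophobic_moment"
        )
    )
    defs.append(FeatureDef("general_length", "general", "scalar", "length"))
    defs.append(
        FeatureDef("general_molecular_weight", "general", "scalar", "molecular_weight")
    )
    defs.append(FeatureDef("pi", "pi", "scalar", "pi"))
    return defs


EXPECTED_CATALOG_SIZE = 146
EXPECTED_FEATURE_SETS = {
    "aa_composition",
    "group_composition",
    "minimotif",
    "ninetad",
    "disorder",
    "helicity",
    "general",
    "pi",
}


def build_default_catalog() -> list[FeatureDef]:
    """Load and validate the bundled 146-feature catalog.

    The catalog ships as a data file so the feature definitions are
    inspectable and stable; missing file, wrong size, duplicated ids or an
    unknown feature set are configuration errors.
    """
    ref = resources.files("tadscreen.data").joinpath("feature_catalog.json")
    try:
        entries = json.loads(ref.read_text())["features"]
    except FileNotFoundError as exc:
        raise RuntimeError("feature catalog data file is missing") from exc
    defs = [FeatureDef(**e) for e in entries]
    ids = [d.feature_id for d in defs]
    if len(set(ids)) != len(ids):
        raise RuntimeError("duplicated feature ids in catalog")
    if len(defs) != EXPECTED_CATALOG_SIZE:
        raise RuntimeError(
            f"catalog must contain {EXPECTED_CATALOG_SIZE} features, got {len(defs)}"
        )
    unknown = {d.feature_set for d in defs} - EXPECTED_FEATURE_SETS
    if unknown:
        raise RuntimeError(f"unknown feature sets in catalog: {sorted(unknown)}")
    return defs


def featurize(peptides, catalog: list[FeatureDef] | None = None):
    """Compute the feature matrix (rows = peptides, columns = features).

    Returns a pandas DataFrame with feature_id columns in catalog order.
    """
    import pandas as pd

    if catalog is None:
        catalog = build_default_catalog()
    rows = [
        [compute_feature(p, fdef) for fdef in catalog] for p in peptides
    ]
    return pd.DataFrame(rows, columns=[d.feature_id for d in catalog])
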