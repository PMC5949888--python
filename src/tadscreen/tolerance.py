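"""Mutational-scanning analytics for designed TAD variant libraries.

Per-TAD tolerance scores (fraction of assayed variants that stay
functional), pooled substitution-tolerance matrices ordered by marginal
tolerance, and handling of point-variant notation such as ``W30R``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import STANDARD_AA, check_peptide

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

VARIANT_COLUMNS = ["tad_id", "position", "wt_aa", "sub_aa", "label"]


@dataclass
class TADSet:
    """A wild-type TAD and its assayed single-substitution variants."""

    tad_id: str
    wt_peptide: str
    variants: pd.DataFrame  # columns: position (1-based), wt_aa, sub_aa, label

    def __post_init__(self):
        check_peptide(self.wt_peptide)
        for row in self.variants.itertuples(index=False):
            if not 1 <= row.position <= len(self.wt_peptide):
                raise ValueError(
                    f"{self.tad_id}: position {row.position} outside 1..{len(self.wt_peptide)}"
                )
            if self.wt_peptide[row.position - 1] != row.wt_aa:
                raise ValueError(
                    f"{self.tad_id}: WT residue at {row.position} is "
                    f"{self.wt_peptide[row.position - 1]}, not {row.wt_aa}"
                )


def tolerance_score(variants: pd.DataFrame) -> float:
    """Fraction of labeled variants that are functional.

    Variants labeled ``missing`` (not detected in the library) are excluded
    from both numerator and denominator.
    """
    labeled = variants[variants["label"].isin(["functional", "nonfunctional"])]
    if len(labeled) == 0:
        raise ValueError("no labeled variants: tolerance undefined")
    return float((labeled["label"] == "functional").mean())


def tolerance_by_tad(variants: pd.DataFrame) -> pd.Series:
    """Per-TAD tolerance scores, sorted by decreasing tolerance."""
    scores = variants.groupby("tad_id").apply(
        tolerance_score, include_groups=False
    )
    return scores.sort_values(ascending=False)


def substitution_matrix(variants: pd.DataFrame) -> pd.DataFrame:
    """Pooled substitution-tolerance matrix.

    Rows are substituted-into residues, columns are WT residues; each cell
    is the fraction of functional variants among all labeled variants with
    that (wt -> sub) substitution, pooled over TADs. Unobserved pairs stay
    empty (NaN), not zero. Rows and columns are ordered by decreasing mean
    of their observed cells.
    """
    labeled = variants[variants["label"].isin(["functional", "nonfunctional"])]
    frac = (
        labeled.assign(functional=labeled["label"] == "functional")
        .groupby(["sub_aa", "wt_aa"])["functional"]
        .mean()
    )
    matrix = frac.unstack("wt_aa")
    row_order = matrix.mean(axis=1, skipna=True).sort_values(ascending=False).index
    col_order = matrix.mean(axis=0, skipna=True).sort_values(ascending=False).index
    return matrix.loc[row_order, col_order]


def parse_variant(notation: str) -> tuple[str, int, str]:
    """Parse ``<wt_aa><position><sub_aa>`` notation (e.g. E135K)."""
    m = _VARIANT_RE.match(notation.strip())
    if not m:
        raise ValueError(f"malformed variant notation: {notation!r}")
    wt_aa, pos, sub_aa = m.group(1), int(m.group(2)), m.group(3)
    if wt_aa not in STANDARD_AA or sub_aa not in STANDARD_AA:
        raise ValueError(f"non-standard residue in variant {notation!r}")
    return wt_aa, pos, sub_aa


def parse_apply_variant(
    notation: str, wt_peptide: str, offset: int = 0
) -> dict:
    """Parse a variant and apply it to a peptide.

    ``offset`` maps protein-level coordinates onto the local peptide
    (local position = position - offset); the notation's WT residue must
    match the peptide at that position. Identity substitutions are applied
    as no-ops but flagged.
    """
    check_peptide(wt_peptide)
    wt_aa, pos, sub_aa = parse_variant(notation)
    local = pos - offset
    if not 1 <= local <= len(wt_peptide):
        raise ValueError(
            f"{notation}: position {pos} (local {local}) outside the peptide"
        )
    if wt_peptide[local - 1] != wt_aa:
        raise ValueError(
            f"{notation}: expected {wt_aa} at position {pos}, "
            f"found {wt_peptide[local - 1]}"
        )
    mutated = wt_peptide[: local - 1] + sub_aa + wt_peptide[local:]
    return {
        "wt_aa": wt_aa,
        "position": pos,
        "local_position": local,
        "sub_aa": sub_aa,
        "mutated_peptide": mutated,
        "is_identity": wt_aa == sub_aa,
    }


def variant_table_from_members(members, labels: dict[str, bool]) -> pd.DataFrame:
    """Assemble the variant label table from design-library members.

    ``labels`` maps member_id to the screen's functional call; members
    absent from it are recorded as ``missing``.
    """
    rows = []
    for m in members:
        if m.variant_pos is None:
            continue
        if m.member_id in labels:
            label = "functional" if labels[m.member_id] else "nonfunctional"
        else:
            label = "missing"
        rows.append(
            {
                "tad_id": m.tad_set_id,
                "position": m.variant_pos,
                "wt_aa": m.variant_wt,
                "sub_aa": m.variant_sub,
                "label": label,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
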