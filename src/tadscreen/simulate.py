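"""Synthetic growth-selection screen generator.

Emulates the data-generating process the downstream analysis assumes: a
random 60-nt insert library (or a designed single-substitution variant
library with stop-codon controls and distance-separated replicate
barcodes), exponential clone growth over the sampling days, multinomial
sequencing at a configured depth, and optional read emission with per-base
substitution errors. Every member carries a hidden ground-truth label and
growth rate so recovery can be tested end to end.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import (
    DNA_ALPHABET,
    STOP_CODONS,
    InvalidAlphabetError,
    back_translate,
    check_dna,
    check_peptide,
    levenshtein,
    translate_insert,
)

#: Stop-codon tail appended in DNA emission mode: a stop in each of the
#: three reading frames, so any frame of the random insert terminates.
DEFAULT_STOP_TAIL = "TAATTAATTAA"

DESIGN_SUBSTITUTIONS = "AGPKR"


class CapacityError(RuntimeError):
    """Barcode rejection sampling could not satisfy the request."""


@dataclass
class LibraryMember:
    """One clone in the screened library."""

    member_id: str
    insert_dna: str
    peptide: str
    origin: str  # random | design_variant | stop_control
    tad_set_id: str | None = None
    barcode: str | None = None
    true_class: str | None = None  # functional | nonfunctional
    true_growth_rate: float | None = None
    # design-variant annotation (1-based position in the WT peptide)
    variant_pos: int | None = None
    variant_wt: str | None = None
    variant_sub: str | None = None

    @property
    def starts_with_stop(self) -> bool:
        return self.insert_dna[:3] in STOP_CODONS


@dataclass
class ScreenDesign:
    """Sampling design of the simulated screen.

    Days and replicate counts follow the screen layout: sampling on days
    0/2/4/6/8 with three replicate experiments for the random library (six
    barcode replicates for the design library).
    """

    time_points: tuple[float, ...] = (0, 2, 4, 6, 8)
    n_replicates: int = 3
    depth: int = 10_000
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        tp = tuple(self.time_points)
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing and start at 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.substitution_error_rate < 0.1:
            raise ValueError("substitution_error_rate must be in [0, 0.1)")
        self.time_points = tp


@dataclass
class GroundTruthRule:
    """Planted functionality rule.

    A peptide is functional iff it has at least ``min_acidic`` acidic
    residues (D/E), at least ``min_aromatic`` aromatic residues (F/W/Y) and
    at most ``max_positive`` positively charged residues (K/R/H) — the
    compositional signature of acidic activation domains. Growth rates are
    per-day exponential rates of clone abundance.
    """

    min_acidic: int = 2
    min_aromatic: int = 1
    max_positive: int = 0
    g_functional: float = 0.05
    g_nonfunctional: float = -0.15

    def __post_init__(self):
        if self.g_functional <= self.g_nonfunctional:
            raise ValueError("g_functional must exceed g_nonfunctional")

    def is_functional(self, peptide: str) -> bool:
        acidic = sum(peptide.count(a) for a in "DE")
        aromatic = sum(peptide.count(a) for a in "FWY")
        positive = sum(peptide.count(a) for a in "KRH")
        return (
            acidic >= self.min_acidic
            and aromatic >= self.min_aromatic
            and positive <= self.max_positive
        )


def validate_stop_tail(tail: str) -> bool:
    """True iff a stop codon occurs in each of the three reading frames."""
    check_dna(tail)
    for frame in range(3):
        codons = [tail[i : i + 3] for i in range(frame, len(tail) - 2, 3)]
        if not any(c in STOP_CODONS for c in codons):
            return False
    return True


def generate_random_inserts(
    n: int, length: int = 60, seed: int | None = None
) -> list[LibraryMember]:
    """Uniform-random DNA inserts (default 60 nt, so peptides are <= 20 aa)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length % 3 != 0:
        raise ValueError("insert length must be divisible by 3")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    members = []
    width = max(6, len(str(n)))
    for i in range(n):
        insert = "".join(rng.choice(bases, size=length))
        peptide, _ = translate_insert(insert)
        members.append(
            LibraryMember(
                member_id=f"rand_{i:0{width}d}",
                insert_dna=insert,
                peptide=peptide,
                origin="random",
            )
        )
    return members


def generate_design_library(
    wt_tads: list[tuple[str, str]],
    substitutions: str = DESIGN_SUBSTITUTIONS,
) -> list[LibraryMember]:
    """Single-substitution scan library over a set of WT TAD peptides.

    For each WT of length L: the WT member plus up to ``len(substitutions)*L``
    single-substitution variants (identity substitutions skipped). Three
    stop-codon control members (first codon TAA/TGA/TAG) are appended per
    library.
    """
    members: list[LibraryMember] = []
    longest = ""
    for tad_id, wt in wt_tads:
        check_peptide(wt)
        if not 8 <= len(wt) <= 30:
            raise ValueError(f"WT peptide {tad_id} must be 8-30 aa, got {len(wt)}")
        if len(wt) > len(longest):
            longest = wt
        members.append(
            LibraryMember(
                member_id=f"{tad_id}_WT",
                insert_dna=back_translate(wt),
                peptide=wt,
                origin="design_variant",
                tad_set_id=tad_id,
            )
        )
        for pos, wt_aa in enumerate(wt, start=1):
            for sub in substitutions:
                if sub == wt_aa:
                    continue
                variant = wt[: pos - 1] + sub + wt[pos:]
                members.append(
                    LibraryMember(
                        member_id=f"{tad_id}_{wt_aa}{pos}{sub}",
                        insert_dna=back_translate(variant),
                        peptide=variant,
                        origin="design_variant",
                        tad_set_id=tad_id,
                        variant_pos=pos,
                        variant_wt=wt_aa,
                        variant_sub=sub,
                    )
                )
    # three stop-codon controls: truncation right at the insert start
    filler = back_translate(longest[1:]) if len(longest) > 1 else ""
    for stop in ("TAA", "TGA", "TAG"):
        members.append(
            LibraryMember(
                member_id=f"stop_{stop}",
                insert_dna=stop + filler,
                peptide="",
                origin="stop_control",
            )
        )
    return members


def generate_barcodes(
    n: int,
    length: int = 8,
    min_lev: int = 4,
    seed: int | None = None,
    max_attempts_per_barcode: int = 20_000,
) -> list[str]:
    """Random barcodes with pairwise Levenshtein distance >= ``min_lev``.

    Bounded rejection sampling; raises :class:`CapacityError` when the
    request cannot be satisfied within the attempt budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    barcodes: list[str] = []
    attempts = 0
    budget = max_attempts_per_barcode * n
    while len(barcodes) < n:
        if attempts >= budget:
            raise CapacityError(
                f"could not place {n} barcodes of length {length} at "
                f"min distance {min_lev} within {budget} attempts"
            )
        attempts += 1
        cand = "".join(rng.choice(bases, size=length))
        if all(levenshtein(cand, b) >= min_lev for b in barcodes):
            barcodes.append(cand)
    return barcodes


def plant_ground_truth(
    member: LibraryMember, rule: GroundTruthRule
) -> LibraryMember:
    """Attach the hidden label and growth rate implied by the planted rule."""
    labeled = dataclasses.replace(member)
    if member.origin == "stop_control" or not rule.is_functional(member.peptide):
        labeled.true_class = "nonfunctional"
        labeled.true_growth_rate = rule.g_nonfunctional
    else:
        labeled.true_class = "functional"
        labeled.true_growth_rate = rule.g_functional
    return labeled


def label_library(
    members: list[LibraryMember], rule: GroundTruthRule
) -> list[LibraryMember]:
    return [plant_ground_truth(m, rule) for m in members]


def expected_proportions(
    members: list[LibraryMember],
    time: float,
    initial_abundance: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form expected sample proportions at a time point."""
    rates = np.array([m.true_growth_rate for m in members], dtype=float)
    a0 = (
        np.full(len(members), 1.0 / len(members))
        if initial_abundance is None
        else np.asarray(initial_abundance, dtype=float)
    )
    abundance = a0 * np.exp(rates * time)
    return abundance / abundance.sum()


def simulate_screen(
    members: list[LibraryMember],
    design: ScreenDesign,
    initial_abundance: str = "uniform",
    lognormal_sigma: float = 1.0,
) -> pd.DataFrame:
    """Simulate the time-course count table of the screen.

    Clone abundance follows ``a_i(t) = a_i(0) * exp(r_i * t)``; each
    (time, replicate) sample draws ``depth`` reads multinomially from the
    abundance proportions. Initial abundances are uniform by default
    (log-normal optional to emulate library skew).

    Returns a long-format table with columns
    ``member_id, sequence, time_day, replicate, count``; each sample's
    counts sum exactly to ``design.depth``.
    """
    if not members:
        raise ValueError("empty member list: nothing to simulate")
    if any(m.true_growth_rate is None for m in members):
        raise ValueError("members must be labeled with true_growth_rate")
    rng = np.random.default_rng(design.seed)
    if initial_abundance == "uniform":
        a0 = np.full(len(members), 1.0 / len(members))
    elif initial_abundance == "lognormal":
        a0 = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(members))
        a0 /= a0.sum()
    else:
        raise ValueError(f"unknown initial_abundance: {initial_abundance!r}")

    rows = []
    for t in design.time_points:
        props = expected_proportions(members, t, a0)
        for rep in range(1, design.n_replicates + 1):
            counts = rng.multinomial(design.depth, props)
            for m, c in zip(members, counts):
                rows.append((m.member_id, m.insert_dna, t, rep, int(c)))
    return pd.DataFrame(
        rows, columns=["member_id", "sequence", "time_day", "replicate", "count"]
    )


def emit_reads(
    members: list[LibraryMember],
    counts: pd.DataFrame,
    design: ScreenDesign,
    with_stop_tail: bool = True,
    phred: int = 30,
) -> list[tuple[str, str, str, float, int]]:
    """Emit per-read records from a simulated count table.

    Each read is the member's insert (barcode-prefixed when the member
    carries one, stop-tail suffixed in DNA emission mode) with i.i.d.
    per-base substitution errors at the configured rate and constant Phred
    quality. Returns tuples ``(read_id, seq, member_id, time_day, replicate)``.
    """
    rng = np.random.default_rng(design.seed + 1)
    by_id = {m.member_id: m for m in members}
    bases = "ACGT"
    reads = []
    i = 0
    for row in counts.itertuples(index=False):
        member = by_id[row.member_id]
        template = member.insert_dna
        if member.barcode:
            template = member.barcode + template
        if with_stop_tail:
            template = template + DEFAULT_STOP_TAIL
        for _ in range(row.count):
            seq = template
            if design.substitution_error_rate > 0:
                arr = list(seq)
                errs = rng.random(len(arr)) < design.substitution_error_rate
                for j in np.flatnonzero(errs):
                    choices = bases.replace(arr[j], "")
                    arr[j] = choices[rng.integers(len(choices))]
                seq = "".join(arr)
            reads.append(
                (f"read_{i:08d}", seq, row.member_id, row.time_day, row.replicate)
            )
            i += 1
    return reads
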