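"""Read processing: merge, filter, demultiplex, trim, dereplicate, cluster, map.

Turns raw reads into a per-centroid count table. The stage mirrors amplicon
pipelines (pair merging, expected-error filtering, barcode demultiplexing
with a Levenshtein tolerance, adaptor trimming, dereplication, abundance-
ordered greedy identity clustering and read-to-centroid mapping), simplified
to the accept/reject contracts that matter downstream rather than any
particular external tool's heuristics.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

import edlib
import pandas as pd

from .seqs import (
    check_dna,
    levenshtein,
    pairwise_identity,
    reverse_complement,
    translate_insert,
)

__all__ = [
    "SequencingRead",
    "CentroidCluster",
    "merge_pairs",
    "expected_errors",
    "ee_filter",
    "assign_barcode",
    "trim_adaptor",
    "dereplicate",
    "greedy_cluster",
    "map_reads",
    "levenshtein",
    "pairwise_identity",
    "translate_insert",
]


@dataclass
class SequencingRead:
    id: str
    seq: str
    quals: list[int]

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"read {self.id}: Phred scores must be in [0, 60]")


@dataclass
class CentroidCluster:
    """Greedy identity cluster: centroid plus supporting dereplicated members."""

    centroid_seq: str
    member_count: int = 0
    members: dict[str, int] = field(default_factory=dict)

    def add(self, seq: str, count: int) -> None:
        self.members[seq] = self.members.get(seq, 0) + count
        self.member_count += count


# ---------------------------------------------------------------------------
# pair merging


def _overlap_offsets(fwd: str, rc_rev: str, k: int = 15) -> list[int]:
    """Candidate fwd->rc offsets from shared exact k-mer seeds."""
    index: dict[str, list[int]] = {}
    for i in range(len(fwd) - k + 1):
        index.setdefault(fwd[i : i + k], []).append(i)
    offsets: set[int] = set()
    for j in range(len(rc_rev) - k + 1):
        for i in index.get(rc_rev[j : j + k], ()):
            off = i - j
            if off >= 0:
                offsets.add(off)
    return sorted(offsets)


def merge_pairs(
    fwd: SequencingRead,
    rev: SequencingRead,
    target_len: int = 60,
    max_gaps: int = 2,
):
    """Overlap-merge a forward read with a reverse-strand read.

    The reverse read is reverse-complemented, candidate overlaps are found
    by exact 15-mer seeding, and the overlap is aligned allowing at most
    ``max_gaps`` indels. Disagreements in the overlap resolve toward the
    higher-quality base. The merge is accepted only when the final sequence
    has exactly ``target_len`` bases.

    Returns a merged :class:`SequencingRead`, or ``(None, reason)`` wrapped
    as a tuple ``(read_or_None, reason)``.
    """
    rc = reverse_complement(rev.seq)
    rc_quals = rev.quals[::-1]
    offsets = _overlap_offsets(fwd.seq, rc)
    if not offsets:
        return None, "no_overlap"
    last_reason = "no_overlap"
    for off in offsets:
        overlap_f = fwd.seq[off:]
        # align the forward overlap against a prefix of the rc read; I/D
        # operations in the alignment path are the merge gaps
        res = edlib.align(overlap_f, rc, mode="SHW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        cigar = res["cigar"] or ""
        gaps = sum(
            int(num)
            for num, op in _CIGAR_RE.findall(cigar)
            if op in "ID"
        )
        rc_overlap_len = res["locations"][0][1] + 1
        if gaps > max_gaps:
            last_reason = "too_many_gaps"
            continue
        if gaps == 0:
            # gapless: column-wise consensus toward the higher-quality base
            merged_seq = list(fwd.seq[:off])
            merged_quals = list(fwd.quals[:off])
            for i in range(rc_overlap_len):
                qf, qr = fwd.quals[off + i], rc_quals[i]
                if qf >= qr:
                    merged_seq.append(overlap_f[i])
                    merged_quals.append(max(qf, qr) if overlap_f[i] == rc[i] else qf)
                else:
                    merged_seq.append(rc[i])
                    merged_quals.append(qr)
            merged = "".join(merged_seq) + rc[rc_overlap_len:]
            merged_quals.extend(rc_quals[rc_overlap_len:])
        else:
            # gapped overlap: take the reverse read's version of the overlap
            merged = fwd.seq[:off] + rc
            merged_quals = list(fwd.quals[:off]) + list(rc_quals)
        if len(merged) != target_len:
            last_reason = "bad_length"
            continue
        return SequencingRead(fwd.id, merged, merged_quals), "merged"
    return None, last_reason


# ---------------------------------------------------------------------------
# quality filtering


def expected_errors(quals: list[int]) -> float:
    """Expected number of errors implied by Phred scores: sum of 10^(-Q/10)."""
    return float(sum(10 ** (-q / 10) for q in quals))


def ee_filter(read: SequencingRead, max_ee: float = 1.0) -> bool:
    """Keep a read iff its expected error count is at most ``max_ee``."""
    return expected_errors(read.quals) <= max_ee


# ---------------------------------------------------------------------------
# demultiplexing and trimming


def _prefix_distance(barcode: str, seq: str) -> tuple[int, int]:
    """Prefix-anchored Levenshtein distance of a barcode to a read 5' end.

    Returns ``(distance, matched_prefix_length)``; the barcode is anchored
    at the read start but may consume a shorter/longer prefix via indels.
    """
    res = edlib.align(barcode, seq, mode="SHW", task="locations")
    end = res["locations"][0][1] + 1 if res["locations"] else len(barcode)
    return res["editDistance"], end


def assign_barcode(
    seq: str, barcodes: list[str], max_err: int | None = None
) -> tuple[str | None, str]:
    """Assign the closest barcode to the read prefix and strip it.

    The default tolerance is a 25% error rate within the barcode
    (floor(0.25 * len) = 2 mistakes for 8-nt barcodes). Ties between two
    barcodes at the minimal distance leave the read unassigned.

    Returns ``(barcode or None, remaining_sequence)``.
    """
    if not barcodes:
        return None, seq
    if max_err is None:
        max_err = int(0.25 * len(barcodes[0]))
    scored = [( *_prefix_distance(b, seq), b) for b in barcodes]
    scored.sort(key=lambda x: (x[0], x[2]))
    best_d, best_end, best_b = scored[0]
    if best_d > max_err:
        return None, seq
    if len(scored) > 1 and scored[1][0] == best_d:
        return None, seq  # ambiguous
    return best_b, seq[best_end:]


def trim_adaptor(
    seq: str, adaptor: str, err_rate: float = 0.10, side: str = "3p"
) -> str | None:
    """Locate and remove an adaptor, tolerating a 10% error rate in it.

    ``floor(err_rate * len(adaptor))`` edits are allowed (2 for the 21-nt
    adaptors). For ``side="3p"`` the adaptor and everything downstream are
    removed; for ``side="5p"`` the adaptor and everything upstream. Reads
    without a locatable adaptor are dropped (``None``).
    """
    check_dna(adaptor)
    max_edits = int(err_rate * len(adaptor))
    res = edlib.align(adaptor, seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_edits:
        return None
    start, end = res["locations"][0]
    if side == "3p":
        return seq[:start]
    if side == "5p":
        return seq[end + 1 :]
    raise ValueError(f"unknown side: {side!r}")


# ---------------------------------------------------------------------------
# dereplication, clustering, mapping


def dereplicate(seqs, min_count: int = 2) -> dict[str, int]:
    """Exact-identity grouping; entries below ``min_count`` are discarded."""
    counts = Counter(seqs)
    return {s: c for s, c in counts.items() if c >= min_count}


def greedy_cluster(
    dereps: dict[str, int], id_threshold: float = 0.90
) -> list[CentroidCluster]:
    """Abundance-ordered greedy identity clustering.

    Sequences are visited by decreasing count (ties lexicographic); each
    joins the first existing centroid with identity >= threshold, else
    founds a new centroid. Founders are the highest-abundance members of
    their cluster by construction.
    """
    clusters: list[CentroidCluster] = []
    for seq, count in sorted(dereps.items(), key=lambda kv: (-kv[1], kv[0])):
        for cluster in clusters:
            if pairwise_identity(seq, cluster.centroid_seq) >= id_threshold:
                cluster.add(seq, count)
                break
        else:
            cluster = CentroidCluster(centroid_seq=seq)
            cluster.add(seq, count)
            clusters.append(cluster)
    return clusters


def _nearest_centroids(seq: str, centroids: list[str], top: int = 3) -> list[str]:
    """Candidate centroids ranked by edit distance (fast prefilter)."""
    scored = sorted(
        centroids,
        key=lambda c: (edlib.align(seq, c, mode="NW", task="distance")["editDistance"], c),
    )
    return scored[:top]


def map_reads(
    reads,
    centroids: list[str],
    id_threshold: float = 0.90,
) -> tuple[pd.DataFrame, int]:
    """Map reads to their highest-identity centroid and tabulate counts.

    ``reads`` is an iterable of ``(seq, time_day, replicate)``. A read is
    assigned to the centroid with the highest end-to-end identity when that
    identity reaches the threshold (0.90 for de novo random-library
    centroids, 0.80 when mapping against designed reference sequences);
    otherwise it is counted as unmapped.

    Returns ``(count table, n_unmapped)`` with columns
    ``sequence, time_day, replicate, count`` (sequence = centroid).
    """
    exact = set(centroids)
    tallies: Counter = Counter()
    unmapped = 0
    cache: dict[str, str | None] = {}
    for seq, time_day, replicate in reads:
        if seq in exact:
            tallies[(seq, time_day, replicate)] += 1
            continue
        if seq in cache:
            hit = cache[seq]
        else:
            best, best_id = None, -1.0
            for cand in _nearest_centroids(seq, centroids):
                ident = pairwise_identity(seq, cand)
                if ident > best_id:
                    best, best_id = cand, ident
            hit = best if best_id >= id_threshold else None
            cache[seq] = hit
        if hit is None:
            unmapped += 1
        else:
            tallies[(hit, time_day, replicate)] += 1
    table = pd.DataFrame(
        [(s, t, r, c) for (s, t, r), c in sorted(tallies.items())],
        columns=["sequence", "time_day", "replicate", "count"],
    )
    return table, unmapped


# ---------------------------------------------------------------------------
# orchestration


def process_reads(
    reads,
    mode: str = "random",
    barcodes: list[str] | None = None,
    adaptor: str | None = None,
    max_ee: float = 1.0,
    min_derep_count: int = 2,
    cluster_identity: float = 0.90,
    design_centroids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the single-end processing pipeline on sample-annotated reads.

    ``reads`` is an iterable of ``(SequencingRead, time_day, replicate)``.
    In ``random`` mode centroids are discovered by dereplication and greedy
    clustering at ``cluster_identity`` and reads are re-mapped against them
    at the same identity; in ``design`` mode reads map directly against
    ``design_centroids`` at identity 0.80.

    Returns ``(count table, per-stage QC dict)``; the QC dict conserves
    reads: input == passed + rejected at each stage.
    """
    if mode not in ("random", "design"):
        raise ValueError(f"unknown mode: {mode!r}")
    qc = {"input": 0, "ee_rejected": 0, "barcode_unassigned": 0, "adaptor_dropped": 0}
    kept: list[tuple[str, float, int]] = []
    for read, time_day, replicate in reads:
        qc["input"] += 1
        if not ee_filter(read, max_ee):
            qc["ee_rejected"] += 1
            continue
        seq = read.seq
        if barcodes is not None:
            bc, seq = assign_barcode(seq, barcodes)
            if bc is None:
                qc["barcode_unassigned"] += 1
                continue
        if adaptor is not None:
            trimmed = trim_adaptor(seq, adaptor)
            if trimmed is None:
                qc["adaptor_dropped"] += 1
                continue
            seq = trimmed
        kept.append((seq, time_day, replicate))

    if mode == "random":
        dereps = dereplicate((s for s, _, _ in kept), min_count=min_derep_count)
        clusters = greedy_cluster(dereps, cluster_identity)
        centroids = [c.centroid_seq for c in clusters]
        map_identity = cluster_identity
    else:
        if not design_centroids:
            raise ValueError("design mode requires design_centroids")
        centroids = list(design_centroids)
        map_identity = 0.80
    table, unmapped = map_reads(kept, centroids, map_identity)
    qc["unmapped"] = unmapped
    qc["mapped"] = int(table["count"].sum()) if len(table) else 0
    qc["n_centroids"] = len(centroids)
    return table, qc
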