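"""Small-RNA locus profiling: trimming, structural filtering, exact alignment,
size-class normalization, 50-bp binning and lost-region calling.

A library moves through a fixed pipeline, with every read accounted for at
each step (raw = no-adapter + length-rejected + structural + non-structural):

1. adapter trimming — the insert is the prefix before the leftmost exact
   match of the adapter's first ``k`` bases; inserts outside [18, 30] nt are
   rejected with a reason;
2. structural filtering — a read is structural when it occurs as an exact
   substring of any tRNA/rRNA/sn/snoRNA reference record or its reverse
   complement; structural reads are excluded from all abundance denominators;
3. perfect-match alignment to a single copy of the locus — all zero-mismatch
   occurrences on both strands; a multicopy gene is profiled as an aggregate
   through its representative copy, so multi-hit reads count at every hit
   (an optional once-per-read mode divides by the hit number);
4. normalization — reads per million (RPM) over locus-matched non-structural
   reads, optionally rescaled so every library shares a reference library's
   22-nt abundance.  The 22-nt class anchors the comparison because an RdDM
   mutant collapses the 24-nt class and thereby inflates every other class
   under plain per-million scaling.
5. binned abundance — hits are counted once per hit in half-open 50-bp bins
   on a grid laid out in TSS-label space (labels skip 0, so the bin
   straddling the TSS is one base short); regions whose 24-nt abundance
   collapses in the mutant are maximal runs of bins with wild-type abundance
   above a floor and mutant/wild-type ratio below a ceiling.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .locus import ReferenceLocus, revcomp, to_tss_coord

__all__ = [
    "SmallRNALibrary",
    "trim_adapter",
    "trim_library",
    "filter_structural",
    "align_perfect",
    "align_library",
    "normalize_libraries",
    "size_distribution",
    "position_coverage",
    "bin_table",
    "mean_bin_abundance",
    "call_lost_regions",
    "read_fastq_counts",
    "read_collapsed_fasta",
    "MIN_INSERT",
    "MAX_INSERT",
]

MIN_INSERT = 18
MAX_INSERT = 30
ADAPTER_SEED_LEN = 8


@dataclass
class SmallRNALibrary:
    """One library's collapsed reads plus full pipeline bookkeeping."""

    id: str
    genotype: str = ""
    replicate: str = ""
    raw_reads: Counter = field(default_factory=Counter)  # raw read -> count
    inserts: Counter = field(default_factory=Counter)    # trimmed insert -> count
    structural: Counter = field(default_factory=Counter)
    retained: Counter = field(default_factory=Counter)   # non-structural inserts
    hits: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        t = self.tallies
        total = (
            t.get("no_adapter", 0)
            + t.get("length_rejected", 0)
            + t.get("structural", 0)
            + t.get("nonstructural", 0)
        )
        if total != t.get("raw", 0):
            raise AssertionError(
                f"library {self.id}: read accounting broken ({total} != {t.get('raw', 0)})"
            )


# ---------------------------------------------------------------------------
# trimming


def trim_adapter(
    read: str,
    adapter: str,
    min_len: int = MIN_INSERT,
    max_len: int = MAX_INSERT,
    k: int = ADAPTER_SEED_LEN,
) -> tuple[str | None, str]:
    """Trim a 3' adapter; returns (insert, "ok") or (None, rejection reason).

    The insert is the read prefix before the leftmost exact occurrence of
    the adapter's first ``k`` bases.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    if not read:
        return None, "no_adapter"
    seed = adapter[:k]
    idx = read.find(seed)
    if idx < 0:
        return None, "no_adapter"
    if idx < min_len:
        return None, "too_short"
    if idx > max_len:
        return None, "too_long"
    return read[:idx], "ok"


def trim_library(
    library: SmallRNALibrary,
    adapter: str,
    min_len: int = MIN_INSERT,
    max_len: int = MAX_INSERT,
    k: int = ADAPTER_SEED_LEN,
) -> SmallRNALibrary:
    tallies = {"raw": 0, "no_adapter": 0, "length_rejected": 0}
    inserts: Counter = Counter()
    for read, count in library.raw_reads.items():
        tallies["raw"] += count
        insert, reason = trim_adapter(read, adapter, min_len, max_len, k)
        if insert is None:
            key = "no_adapter" if reason == "no_adapter" else "length_rejected"
            tallies[key] += count
        else:
            inserts[insert] += count
    library.inserts = inserts
    library.tallies.update(tallies)
    return library


# ---------------------------------------------------------------------------
# structural filtering


def filter_structural(
    library: SmallRNALibrary, structural_records: Sequence[tuple[str, str]]
) -> SmallRNALibrary:
    """Partition trimmed inserts into structural and retained (non-structural)."""
    fwd = "#".join(seq.upper() for _, seq in structural_records)
    rev = "#".join(revcomp(seq.upper()) for _, seq in structural_records)
    structural: Counter = Counter()
    retained: Counter = Counter()
    for insert, count in library.inserts.items():
        if fwd and (insert in fwd or insert in rev):
            structural[insert] += count
        else:
            retained[insert] += count
    library.structural = structural
    library.retained = retained
    library.tallies["structural"] = sum(structural.values())
    library.tallies["nonstructural"] = sum(retained.values())
    return library


# ---------------------------------------------------------------------------
# alignment


def align_perfect(read: str, locus: ReferenceLocus | str) -> list[tuple[int, str]]:
    """All zero-mismatch hits of a read on the locus, both strands.

    Returns (1-based array position of the leftmost spanned base, strand),
    sorted by position then strand.  A reverse-complement-palindromic read
    present once yields one '+' and one '-' hit at the same position.
    """
    seq = locus.sequence if isinstance(locus, ReferenceLocus) else locus
    hits: list[tuple[int, str]] = []
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        start = seq.find(query)
        while start >= 0:
            hits.append((start + 1, strand))
            start = seq.find(query, start + 1)
    hits.sort()
    return hits


def align_library(library: SmallRNALibrary, locus: ReferenceLocus) -> SmallRNALibrary:
    hits: dict[str, list[tuple[int, str]]] = {}
    matched = 0
    unmatched = 0
    for insert, count in library.retained.items():
        h = align_perfect(insert, locus)
        if h:
            hits[insert] = h
            matched += count
        else:
            unmatched += count
    library.hits = hits
    library.tallies["locus_matched"] = matched
    library.tallies["unmatched"] = unmatched
    return library


# ---------------------------------------------------------------------------
# normalization


def _length_count(library: SmallRNALibrary, length: int, over: str) -> int:
    pool = library.retained if over == "nonstructural" else library.inserts
    if over == "locus_matched":
        return sum(c for s, c in library.retained.items() if len(s) == length and s in library.hits)
    return sum(c for s, c in pool.items() if len(s) == length)


def normalize_libraries(
    libraries: Sequence[SmallRNALibrary],
    mode: str = "rpm",
    reference_library: str = "first",
    anchor_length: int = 22,
    anchor_over: str = "locus_matched",
) -> dict[str, float]:
    """Per-library scale factors: plain RPM, or RPM anchored to the 22-nt class.

    The RPM denominator is each library's locus-matched non-structural read
    count.  In ``rpm_22anchor`` mode the RPM factor is further multiplied by
    (reference library's 22-nt RPM) / (this library's 22-nt RPM), so all
    libraries end up sharing the reference's 22-nt abundance.
    ``anchor_over`` selects the read pool for the 22-nt tally
    (``locus_matched``, ``nonstructural`` or ``trimmed``).
    """
    if mode not in ("rpm", "rpm_22anchor"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    factors: dict[str, float] = {}
    rpm: dict[str, float] = {}
    anchor_rpm: dict[str, float] = {}
    for lib in libraries:
        denom = lib.tallies.get("locus_matched", 0)
        if denom <= 0:
            raise ValueError(f"library {lib.id}: zero normalization denominator")
        rpm[lib.id] = 1e6 / denom
        if mode == "rpm_22anchor":
            n22 = _length_count(lib, anchor_length, anchor_over)
            if n22 <= 0:
                raise ValueError(f"library {lib.id}: zero {anchor_length}-nt class")
            anchor_rpm[lib.id] = n22 * rpm[lib.id]
    if mode == "rpm":
        return dict(rpm)
    ref_id = libraries[0].id if reference_library == "first" else reference_library
    if ref_id not in anchor_rpm:
        raise ValueError(f"reference library {ref_id!r} not among libraries")
    for lib in libraries:
        factors[lib.id] = rpm[lib.id] * anchor_rpm[ref_id] / anchor_rpm[lib.id]
    return factors


def size_distribution(
    library: SmallRNALibrary,
    factor: float | None = None,
    min_len: int = MIN_INSERT,
    max_len: int = MAX_INSERT,
) -> pd.DataFrame:
    """Per-length abundance over locus-matched non-structural reads.

    Columns: length, raw, rpm, and (when ``factor`` is given) the abundance
    under that externally supplied scale factor.
    """
    denom = library.tallies.get("locus_matched", 0)
    counts = {length: 0 for length in range(min_len, max_len + 1)}
    for insert, count in library.retained.items():
        if insert in library.hits and len(insert) in counts:
            counts[len(insert)] += count
    rows = []
    for length in range(min_len, max_len + 1):
        raw = counts[length]
        row = dict(length=length, raw=raw, rpm=(raw * 1e6 / denom) if denom else 0.0)
        if factor is not None:
            row["scaled"] = raw * factor
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage and binning


def position_coverage(
    library: SmallRNALibrary,
    locus: ReferenceLocus,
    size_class: int | None = None,
    strand: str | None = None,
    factor: float = 1.0,
    once_per_read: bool = False,
) -> np.ndarray:
    """Per-position scaled abundance track (index 0 = array position 1).

    Every hit contributes its read's scaled count to every base it spans.
    """
    track = np.zeros(len(locus), dtype=float)
    for insert, hits in library.hits.items():
        if size_class is not None and len(insert) != size_class:
            continue
        count = library.retained[insert] * factor
        if once_per_read and len(hits) > 1:
            count /= len(hits)
        for pos, hit_strand in hits:
            if strand is not None and hit_strand != strand:
                continue
            track[pos - 1 : pos - 1 + len(insert)] += count
    return track


def _bin_index(label: int, anchor: int, width: int) -> int:
    return (label - anchor) // width


def bin_table(
    libraries: Sequence[SmallRNALibrary],
    locus: ReferenceLocus,
    factors: Mapping[str, float],
    width: int = 50,
    anchor: int | None = None,
    size_classes: Sequence[int] = (24,),
    once_per_read: bool = False,
) -> pd.DataFrame:
    """Binned, strand-split, size-resolved abundance table across the locus.

    Bins are half-open [edge, edge + width) on a grid in TSS-label space
    (edges satisfy label ≡ anchor mod width; labels skip 0, so edge values
    are boundaries and an edge of 0 denotes the TSS boundary itself).  A hit
    is assigned to the bin containing its biological 5' end, counted once per
    hit.  ``anchor`` defaults to the label of array position 1, so bins tile
    the locus from its first base.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    tss = locus.tss_array_pos
    if anchor is None:
        anchor = to_tss_coord(1, tss)
    first = _bin_index(to_tss_coord(1, tss), anchor, width)
    last = _bin_index(to_tss_coord(len(locus), tss), anchor, width)
    n_bins = last - first + 1

    columns: dict[str, np.ndarray] = {}
    for lib in libraries:
        factor = factors[lib.id]
        for size in size_classes:
            for strand in ("+", "-"):
                columns[f"{lib.id}|{size}|{strand}"] = np.zeros(n_bins)
        for insert, hits in lib.hits.items():
            size = len(insert)
            if size not in size_classes:
                continue
            count = lib.retained[insert] * factor
            if once_per_read and len(hits) > 1:
                count /= len(hits)
            for pos, strand in hits:
                five_prime = pos if strand == "+" else pos + size - 1
                k = _bin_index(to_tss_coord(five_prime, tss), anchor, width) - first
                if 0 <= k < n_bins:
                    columns[f"{lib.id}|{size}|{strand}"][k] += count

    rows = {
        "bin_index": np.arange(first, last + 1),
        "tss_start": np.array([anchor + k * width for k in range(first, last + 1)]),
        "tss_end": np.array([anchor + (k + 1) * width for k in range(first, last + 1)]),
    }
    rows.update(columns)
    table = pd.DataFrame(rows)
    for lib in libraries:
        for size in size_classes:
            table[f"{lib.id}|{size}|both"] = (
                table[f"{lib.id}|{size}|+"] + table[f"{lib.id}|{size}|-"]
            )
    return table


def mean_bin_abundance(
    bins: pd.DataFrame, library_ids: Sequence[str], size_class: int = 24
) -> pd.DataFrame:
    """Replicate-mean combined-strand abundance per bin for a set of libraries."""
    cols = [f"{lib}|{size_class}|both" for lib in library_ids]
    out = bins[["bin_index", "tss_start", "tss_end"]].copy()
    out["abundance"] = bins[cols].mean(axis=1)
    return out


def call_lost_regions(
    wt_bins: pd.DataFrame,
    mut_bins: pd.DataFrame,
    min_wt: float = 5.0,
    max_ratio: float = 0.2,
    locus: ReferenceLocus | None = None,
) -> pd.DataFrame:
    """Maximal runs of bins whose abundance collapses in the mutant.

    A bin is flagged when wild-type abundance >= ``min_wt`` and the
    mutant/wild-type ratio <= ``max_ratio`` (a mutant abundance of 0 always
    passes the ratio test).  Adjacent flagged bins merge; overlapping feature
    names are attached when a locus is given.  Inputs are replicate-mean
    tables from :func:`mean_bin_abundance` and must share the bin grid.
    """
    if not (
        len(wt_bins) == len(mut_bins)
        and (wt_bins["bin_index"].values == mut_bins["bin_index"].values).all()
        and (wt_bins["tss_start"].values == mut_bins["tss_start"].values).all()
    ):
        raise ValueError("wild-type and mutant bin tables are on different grids")

    wt = wt_bins["abundance"].values
    mut = mut_bins["abundance"].values
    flagged = (wt >= min_wt) & ((mut == 0) | (mut <= max_ratio * wt))

    regions = []
    i = 0
    idx = wt_bins["bin_index"].values
    while i < len(flagged):
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flagged) and flagged[j + 1] and idx[j + 1] == idx[j] + 1:
            j += 1
        start = int(wt_bins["tss_start"].iloc[i])
        end = int(wt_bins["tss_end"].iloc[j])
        wt_sum = float(wt[i : j + 1].sum())
        mut_sum = float(mut[i : j + 1].sum())
        names = ""
        if locus is not None:
            # edges are boundaries; the rightmost contained label is end - 1 (or -1 at the TSS boundary)
            lo = start if start != 0 else 1
            hi = end - 1 if end - 1 != 0 else -1
            names = ",".join(f.name for f in locus.features_overlapping(lo, hi))
        regions.append(
            dict(
                feature=names,
                tss_start=start,
                tss_end=end,
                wt_abundance=wt_sum,
                mut_abundance=mut_sum,
                ratio=(mut_sum / wt_sum) if wt_sum else float("nan"),
            )
        )
        i = j + 1
    return pd.DataFrame(
        regions,
        columns=["feature", "tss_start", "tss_end", "wt_abundance", "mut_abundance", "ratio"],
    )


# ---------------------------------------------------------------------------
# input parsing


def read_fastq_counts(text: str) -> Counter:
    counts: Counter = Counter()
    for rec in SeqIO.parse(io.StringIO(text), "fastq"):
        counts[str(rec.seq).upper()] += 1
    return counts


def read_collapsed_fasta(text: str) -> Counter:
    """Collapsed FASTA where the header's last '_'- or 'x'-separated field is the count."""
    counts: Counter = Counter()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = rec.id
        count = 1
        for sep in ("_x", "-", "_"):
            if sep in header:
                tail = header.rsplit(sep, 1)[-1]
                if tail.isdigit():
                    count = int(tail)
                    break
        counts[str(rec.seq).upper()] += count
    return counts
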