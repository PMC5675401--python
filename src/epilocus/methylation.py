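"""Clone-based bisulfite methylation calling, aggregation and genotype contrasts.

Given sets of gap-free, amplicon-length bisulfite clone sequences, each
cytosine site on the read strand is called methylated (clone base C),
unmethylated (T), or ambiguous (anything else — sequencing error or SNP).
Calls are pooled over the clones of a plant and summarized per context
(CG/CHG/CHH) and per annotated sub-region; genotypes are compared at the
biological-replicate (plant) level with a classical two-sample, two-sided,
equal-variance Student's t-test, significant at P <= 0.05.

The per-context percent is the number of methylated calls divided by the
number of informative (methylated + unmethylated) calls, times 100; ambiguous
calls drop out of both numerator and denominator, and a context with no
informative calls has its percent reported as missing rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .locus import Context, CytosineSite, ReferenceLocus
from .simulate import CloneSet

__all__ = [
    "CallState",
    "MethylationCall",
    "MethylationProfile",
    "GenotypeComparison",
    "call_methylation",
    "summarize_profile",
    "compare_genotypes",
    "per_site_table",
    "profile_clone_set",
]

SIGNIFICANCE_LEVEL = 0.05
AMBIGUITY_WARN_RATE = 0.10

CONTEXTS = (Context.CG, Context.CHG, Context.CHH)


class CallState(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MethylationCall:
    site: CytosineSite
    clone_index: int
    state: CallState


@dataclass
class ContextTally:
    meth: int = 0
    total: int = 0  # informative calls only

    @property
    def percent(self) -> float | None:
        if self.total == 0:
            return None
        return 100.0 * self.meth / self.total


@dataclass
class MethylationProfile:
    """Pooled methylation summary for one clone set (one plant, one amplicon)."""

    clone_set_id: str
    n_clones: int
    per_site: pd.DataFrame  # tss_pos, strand, context, n_meth, n_unmeth, n_ambig, fraction
    per_context: dict[str, ContextTally]
    per_feature: dict[str, dict[str, ContextTally]]
    flagged_clones: list[int] = field(default_factory=list)

    def percent(self, context: Context | str) -> float | None:
        key = context.value if isinstance(context, Context) else context
        tally = self.per_context.get(key)
        return tally.percent if tally else None


@dataclass
class GenotypeComparison:
    context: str
    genotypes: tuple[str, str]
    replicate_percents: dict[str, list[float]]
    means: dict[str, float]
    sems: dict[str, float | None]  # None with a single replicate
    t_statistic: float | None
    p_value: float | None
    significant: bool | None
    note: str = ""


def call_methylation(
    clone_set: CloneSet, sites: Sequence[CytosineSite]
) -> list[MethylationCall]:
    """One call per (site, clone): C -> methylated, T -> unmethylated, else ambiguous."""
    a_start, a_end = clone_set.amplicon
    for site in sites:
        if site.strand != clone_set.strand:
            raise ValueError(
                f"site at tss {site.tss_pos} is on {site.strand!r}, clone set reads {clone_set.strand!r}"
            )
        if not _within(site.tss_pos, a_start, a_end):
            raise ValueError(f"site at tss {site.tss_pos} outside amplicon {clone_set.amplicon}")

    amp_len = _span_length(a_start, a_end)
    calls: list[MethylationCall] = []
    for clone_index, clone in enumerate(clone_set.clones):
        if len(clone) != amp_len:
            raise ValueError(
                f"clone {clone_index} length {len(clone)} != amplicon length {amp_len}"
            )
        for site in sites:
            offset = _read_offset(site.tss_pos, a_start, a_end, clone_set.strand)
            base = clone[offset]
            if base == "C":
                state = CallState.METHYLATED
            elif base == "T":
                state = CallState.UNMETHYLATED
            else:
                state = CallState.AMBIGUOUS
            calls.append(MethylationCall(site=site, clone_index=clone_index, state=state))
    return calls


def _linear(tss_pos: int) -> int:
    # collapse the no-zero label line onto plain integers for length math
    return tss_pos if tss_pos < 0 else tss_pos - 1


def _within(tss_pos: int, start: int, end: int) -> bool:
    return _linear(start) <= _linear(tss_pos) <= _linear(end)


def _span_length(start: int, end: int) -> int:
    return _linear(end) - _linear(start) + 1


def _read_offset(tss_pos: int, start: int, end: int, strand: str) -> int:
    if strand == "+":
        return _linear(tss_pos) - _linear(start)
    return _linear(end) - _linear(tss_pos)


def summarize_profile(
    calls: Sequence[MethylationCall],
    sites: Sequence[CytosineSite],
    feature_subsets: Mapping[str, tuple[int, int]] | None = None,
    clone_set_id: str = "",
    n_clones: int | None = None,
) -> MethylationProfile:
    """Pool calls over clones into per-site, per-context and per-feature tallies.

    ``feature_subsets`` maps a label (e.g. "Int2-1") to an inclusive
    TSS-relative interval; a site belongs to a subset when its tss_pos falls
    inside that interval.
    """
    if n_clones is None:
        n_clones = 1 + max((c.clone_index for c in calls), default=-1)

    per_site_counts: dict[tuple[int, str], list[int]] = {
        (s.tss_pos, s.strand): [0, 0, 0] for s in sites
    }
    per_context = {ctx.value: ContextTally() for ctx in CONTEXTS}
    subsets = dict(feature_subsets or {})
    per_feature = {
        name: {ctx.value: ContextTally() for ctx in CONTEXTS} for name in subsets
    }
    per_clone_ambig: dict[int, int] = {}

    for call in calls:
        key = (call.site.tss_pos, call.site.strand)
        rec = per_site_counts[key]
        if call.state is CallState.METHYLATED:
            rec[0] += 1
        elif call.state is CallState.UNMETHYLATED:
            rec[1] += 1
        else:
            rec[2] += 1
            per_clone_ambig[call.clone_index] = per_clone_ambig.get(call.clone_index, 0) + 1
        ctx = call.site.context
        if ctx is Context.UNKNOWN or call.state is CallState.AMBIGUOUS:
            continue
        meth = int(call.state is CallState.METHYLATED)
        tally = per_context[ctx.value]
        tally.meth += meth
        tally.total += 1
        for name, (start, end) in subsets.items():
            if _within(call.site.tss_pos, start, end):
                ftally = per_feature[name][ctx.value]
                ftally.meth += meth
                ftally.total += 1

    rows = []
    for site in sites:
        n_meth, n_unmeth, n_ambig = per_site_counts[(site.tss_pos, site.strand)]
        informative = n_meth + n_unmeth
        rows.append(
            dict(
                tss_pos=site.tss_pos,
                strand=site.strand,
                context=site.context.value,
                n_meth=n_meth,
                n_unmeth=n_unmeth,
                n_ambig=n_ambig,
                fraction=(n_meth / informative) if informative else float("nan"),
            )
        )
    per_site = pd.DataFrame(
        rows,
        columns=["tss_pos", "strand", "context", "n_meth", "n_unmeth", "n_ambig", "fraction"],
    )

    n_sites = len(sites)
    flagged = sorted(
        idx
        for idx, n_amb in per_clone_ambig.items()
        if n_sites and n_amb / n_sites > AMBIGUITY_WARN_RATE
    )
    return MethylationProfile(
        clone_set_id=clone_set_id,
        n_clones=n_clones,
        per_site=per_site,
        per_context=per_context,
        per_feature=per_feature,
        flagged_clones=flagged,
    )


def profile_clone_set(
    clone_set: CloneSet,
    sites: Sequence[CytosineSite],
    feature_subsets: Mapping[str, tuple[int, int]] | None = None,
) -> MethylationProfile:
    """Convenience: call and summarize one clone set in a single step."""
    calls = call_methylation(clone_set, sites)
    return summarize_profile(
        calls,
        sites,
        feature_subsets,
        clone_set_id=clone_set.replicate_id,
        n_clones=len(clone_set.clones),
    )


def compare_genotypes(
    profiles: Mapping[tuple[str, str], MethylationProfile],
    context: Context | str,
    feature: str | None = None,
) -> GenotypeComparison:
    """Compare two genotypes' per-context percents at the replicate level.

    Replicate-level pooled percents are the observations; with >= 2 biological
    replicates in each group a classical equal-variance two-sided t-test is
    run.  With a single replicate in either group the comparison is reported
    without t/P and flagged (as for a single-plant control sample).
    """
    key = context.value if isinstance(context, Context) else context
    by_genotype: dict[str, list[float]] = {}
    for (genotype, _replicate), profile in profiles.items():
        if feature is None:
            pct = profile.percent(key)
        else:
            tally = profile.per_feature.get(feature, {}).get(key)
            pct = tally.percent if tally else None
        if pct is not None:
            by_genotype.setdefault(genotype, []).append(pct)
    if len(by_genotype) != 2:
        raise ValueError(f"need exactly 2 genotypes, found {sorted(by_genotype)}")
    g_a, g_b = sorted(by_genotype)
    a = np.asarray(by_genotype[g_a], dtype=float)
    b = np.asarray(by_genotype[g_b], dtype=float)

    means = {g_a: float(a.mean()), g_b: float(b.mean())}
    sems = {
        g: (float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) >= 2 else None)
        for g, v in ((g_a, a), (g_b, b))
    }
    if len(a) < 2 or len(b) < 2:
        return GenotypeComparison(
            context=key,
            genotypes=(g_a, g_b),
            replicate_percents={g_a: list(a), g_b: list(b)},
            means=means,
            sems=sems,
            t_statistic=None,
            p_value=None,
            significant=None,
            note="single replicate in one group; no test performed",
        )
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        t_stat, p_val = 0.0, 1.0  # identical constant groups: no evidence of difference
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
    return GenotypeComparison(
        context=key,
        genotypes=(g_a, g_b),
        replicate_percents={g_a: list(a), g_b: list(b)},
        means=means,
        sems=sems,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        significant=bool(p_val <= SIGNIFICANCE_LEVEL),
    )


def per_site_table(profiles: Mapping[tuple[str, str], MethylationProfile]) -> pd.DataFrame:
    """Per-site fractions for plotting, clone-pooled across each genotype's replicates.

    One record per (site, genotype): tss_pos, strand, context, fraction and
    the number of informative clone calls behind it, sorted by tss_pos then
    genotype.
    """
    pooled: dict[tuple[int, str, str, str], list[int]] = {}
    for (genotype, _rep), profile in profiles.items():
        for row in profile.per_site.itertuples(index=False):
            key = (row.tss_pos, row.strand, row.context, genotype)
            rec = pooled.setdefault(key, [0, 0])
            rec[0] += row.n_meth
            rec[1] += row.n_meth + row.n_unmeth
    rows = []
    for (tss_pos, strand, context, genotype), (meth, informative) in pooled.items():
        rows.append(
            dict(
                tss_pos=tss_pos,
                strand=strand,
                context=context,
                genotype=genotype,
                fraction=(meth / informative) if informative else float("nan"),
                n_informative=informative,
            )
        )
    table = pd.DataFrame(
        rows, columns=["tss_pos", "strand", "context", "genotype", "fraction", "n_informative"]
    )
    if len(table):
        table = table.sort_values(
            ["tss_pos", "genotype"], key=lambda c: c.map(_linear) if c.name == "tss_pos" else c
        ).reset_index(drop=True)
    return table
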