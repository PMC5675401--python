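"""Synthetic locus, bisulfite-clone, small-RNA and Ct-table generators.

Every downstream stage of the package is testable without any sequencing
download: this module builds a multicopy-gene locus of the kind the analysis
targets (a ~10 kb maize gene with transposon fragments in its regulatory
regions), simulates bisulfite amplicon clone sets with per-region/per-context
methylation probabilities, simulates small-RNA libraries whose 24-nt
heterochromatic class collapses at planted RdDM source loci in the mutant
genotype, and simulates qPCR/ChIP Ct tables — all with the planted ground
truth recorded in a :class:`SyntheticTruth` so that recovery can be checked.

The generators model:

* bisulfite chemistry as "methylated C survives, unmethylated C reads as T
  with probability ``conversion_rate``" (incomplete conversion leaves C);
* small-RNA libraries as mixtures of locus-derived source reads (uniform
  start within each source interval, length from a per-source size-class mix,
  strand from a strand mix, abundance scaled per genotype), structural-RNA
  fragments (tRNA/rRNA/sn/snoRNA), and an unmatchable noise fraction; reads
  are emitted as insert + 3' adapter truncated to the read length;
* qPCR Ct values as Gaussian noise around cycle-threshold differences implied
  by the planted relative-expression effects.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus import (
    Context,
    CytosineSite,
    Feature,
    FeatureClass,
    ReferenceLocus,
    enumerate_sites,
    infer_feature_class,
    revcomp,
    to_tss_coord,
)

__all__ = [
    "SirnaSource",
    "SyntheticTruth",
    "CloneSet",
    "SimulatedLibrary",
    "default_locus_config",
    "default_truth_config",
    "build_locus",
    "simulate_clones",
    "simulate_srna_libraries",
    "make_structural_reference",
    "simulate_expression_ct",
    "simulate_chip_ct",
    "TRUSEQ_ADAPTER",
]

TRUSEQ_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SirnaSource:
    """A planted siRNA-producing interval (inclusive TSS-relative coords)."""

    name: str
    start: int
    end: int
    plus_fraction: float  # strand mix: probability a read is sense
    size_mix: dict[int, float]  # read length -> probability, sums to 1
    weights: dict[str, float]  # genotype -> relative abundance weight

    def __post_init__(self) -> None:
        if not 0.0 <= self.plus_fraction <= 1.0:
            raise ValueError(f"source {self.name}: plus_fraction outside [0,1]")
        total = sum(self.size_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"source {self.name}: size mix sums to {total}, not 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"source {self.name}: negative genotype weight")


@dataclass
class SyntheticTruth:
    """Planted ground truth recovered by the acceptance checks."""

    region_meth: dict[str, dict[str, dict[str, float]]]  # feature -> context -> genotype -> p
    conversion_rate: float
    seq_error_rate: float
    sirna_sources: list[SirnaSource]
    structural_fraction: float
    noise_fraction: float
    no_adapter_fraction: float
    expression_effect: dict[str, float]  # genotype -> true relative expression

    def __post_init__(self) -> None:
        for feat, per_ctx in self.region_meth.items():
            for ctx, per_geno in per_ctx.items():
                for geno, p in per_geno.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"region_meth[{feat}][{ctx}][{geno}] = {p} outside [0,1]"
                        )
        for name, val in (
            ("conversion_rate", self.conversion_rate),
            ("seq_error_rate", self.seq_error_rate),
            ("structural_fraction", self.structural_fraction),
            ("noise_fraction", self.noise_fraction),
            ("no_adapter_fraction", self.no_adapter_fraction),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} = {val} outside [0,1]")

    def meth_probability(self, locus: ReferenceLocus, site: CytosineSite, genotype: str) -> float:
        """Planted probability for a site: smallest containing feature with an entry, else background."""
        if site.context is Context.UNKNOWN:
            return 0.0
        best: tuple[int, str] | None = None
        for feat in locus.features_overlapping(site.tss_pos, site.tss_pos):
            if feat.name in self.region_meth:
                span = locus.from_tss(feat.end) - locus.from_tss(feat.start)
                if best is None or span < best[0]:
                    best = (span, feat.name)
        key = best[1] if best else "background"
        per_ctx = self.region_meth.get(key) or self.region_meth["background"]
        per_geno = per_ctx[site.context.value]
        if genotype not in per_geno:
            raise KeyError(f"unknown genotype {genotype!r} in region_meth[{key}]")
        return per_geno[genotype]

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class CloneSet:
    """One plant's set of sequenced bisulfite clones for one amplicon.

    Clones are stored in read-strand orientation: for a '-' amplicon each
    clone is the reverse complement of the array-orientation region, so the
    C (methylated) / T (converted) readout applies uniformly.
    """

    genotype: str
    replicate_id: str
    amplicon: tuple[int, int]  # inclusive TSS-relative interval
    strand: str
    clones: list[str]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("clone set is empty")
        length = None
        for clone in self.clones:
            if length is None:
                length = len(clone)
            elif len(clone) != length:
                raise ValueError("clones differ in length")


# ---------------------------------------------------------------------------
# locus construction


def default_locus_config() -> dict:
    """Feature plan for the default synthetic locus.

    The layout emulates a ~10 kb multicopy maize gene: a distal enhancer
    ~5 kb upstream with no siRNA source, a proximal enhancer immediately
    upstream of the TSS carrying a MULE fragment with inverted repeats,
    three exons, and intron-2 sub-regions (Int2-1/Int2-2) with a
    Stowaway-like MITE overlapping the end of Int2-2.
    """
    return {
        "id": "synthetic_p1_locus",
        "length": 12000,
        "tss_array_pos": 6001,
        "gc_fraction": 0.47,
        "features": [
            # (name, class, tss_start, tss_end)
            ("distal_enhancer", "enhancer", -5135, -4637),
            ("Tourist", "transposon", -1726, -1677),
            ("proximal_enhancer", "enhancer", -600, -1),
            ("MULE", "transposon", -376, -127),
            ("exon1", "exon", 1, 450),
            ("intron1", "other", 451, 1100),
            ("exon2", "exon", 1101, 1700),
            ("intron2", "other", 1701, 5200),
            ("Harbinger", "transposon", 2274, 2323),
            ("hAT", "transposon", 3424, 3523),
            ("Int2-1", "intron_subregion", 4582, 4777),
            ("Int2-2", "intron_subregion", 4778, 5068),
            ("Stowaway", "transposon", 5024, 5123),
            ("exon3", "exon", 5324, 5800),
        ],
        # inverted repeats embedded in transposon fragments (arm length in bp)
        "inverted_repeats": {"MULE": 60, "Stowaway": 25},
    }


def default_truth_config() -> dict:
    """Default planted parameters.

    Methylation probabilities echo the regimes seen at this kind of locus
    (symmetric-high / asymmetric-low at the distal enhancer; a CHG/CHH-rich
    intron-2 sub-region that loses methylation in the RdDM mutant); siRNA
    sources sit on the transposon fragments, with the 24-nt class depleted or
    abolished in the mutant, plus two 21/22-nt sources that are unaffected by
    the mutation and anchor the 22-nt normalization.
    """
    hc24 = {21: 0.03, 22: 0.05, 23: 0.07, 24: 0.80, 25: 0.05}
    mir = {20: 0.10, 21: 0.35, 22: 0.40, 23: 0.15}
    return {
        "region_meth": {
            "distal_enhancer": {
                "CG": {"wildtype": 0.94, "mutant": 0.85},
                "CHG": {"wildtype": 0.85, "mutant": 0.80},
                "CHH": {"wildtype": 0.07, "mutant": 0.04},
            },
            "proximal_enhancer": {
                "CG": {"wildtype": 0.90, "mutant": 0.85},
                "CHG": {"wildtype": 0.80, "mutant": 0.70},
                "CHH": {"wildtype": 0.35, "mutant": 0.10},
            },
            "Int2-1": {
                "CG": {"wildtype": 0.80, "mutant": 0.78},
                "CHG": {"wildtype": 0.55, "mutant": 0.52},
                "CHH": {"wildtype": 0.12, "mutant": 0.11},
            },
            "Int2-2": {
                "CG": {"wildtype": 0.85, "mutant": 0.80},
                "CHG": {"wildtype": 0.72, "mutant": 0.41},
                "CHH": {"wildtype": 0.46, "mutant": 0.20},
            },
            "Stowaway": {
                "CG": {"wildtype": 0.90, "mutant": 0.85},
                "CHG": {"wildtype": 0.75, "mutant": 0.50},
                "CHH": {"wildtype": 0.50, "mutant": 0.25},
            },
            "background": {
                "CG": {"wildtype": 0.60, "mutant": 0.60},
                "CHG": {"wildtype": 0.40, "mutant": 0.40},
                "CHH": {"wildtype": 0.05, "mutant": 0.05},
            },
        },
        "conversion_rate": 0.99,
        "seq_error_rate": 0.001,
        "sirna_sources": [
            dict(name="Tourist", start=-1726, end=-1677, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 6.0, "mutant": 0.08}),
            dict(name="MULE", start=-376, end=-127, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 20.0, "mutant": 0.5}),
            dict(name="hAT", start=3424, end=3523, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 2.0, "mutant": 0.0}),
            dict(name="Int2-2", start=4824, end=4873, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 1.0, "mutant": 0.0}),
            dict(name="Stowaway", start=5024, end=5123, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 7.0, "mutant": 0.6}),
            dict(name="exon3", start=5324, end=5373, plus_fraction=0.5, size_mix=hc24,
                 weights={"wildtype": 0.6, "mutant": 0.0}),
            dict(name="mir_exon1", start=100, end=220, plus_fraction=0.7, size_mix=mir,
                 weights={"wildtype": 8.0, "mutant": 8.0}),
            dict(name="mir_intron1", start=600, end=760, plus_fraction=0.3, size_mix=mir,
                 weights={"wildtype": 8.0, "mutant": 8.0}),
        ],
        "structural_fraction": 0.15,
        "noise_fraction": 0.05,
        "no_adapter_fraction": 0.02,
        "expression_effect": {"wildtype": 1.0, "mutant": 3.5},
    }


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=probs)


def build_locus(
    config: Mapping | None = None,
    seed: int = 0,
    truth_config: Mapping | None = None,
) -> tuple[ReferenceLocus, SyntheticTruth]:
    """Generate the synthetic locus and its planted truth, deterministically.

    Raises if the config has no features, if exon features overlap each
    other, or if any planted probability is outside [0, 1].
    """
    cfg = dict(default_locus_config())
    cfg.update(config or {})
    tcfg = dict(default_truth_config())
    tcfg.update(truth_config or {})

    feats_cfg = cfg["features"]
    if not feats_cfg:
        raise ValueError("locus config declares no features")
    length = int(cfg["length"])
    tss = int(cfg["tss_array_pos"])

    rng = np.random.default_rng(seed)
    arr = _random_dna(rng, length, float(cfg["gc_fraction"]))

    features: list[Feature] = []
    exon_spans: list[tuple[int, int]] = []
    for name, klass, start, end in feats_cfg:
        feat = Feature(name=name, klass=FeatureClass(klass), start=start, end=end)
        features.append(feat)
        if feat.klass is FeatureClass.EXON:
            a0 = start + tss - 1 if start > 0 else start + tss
            a1 = end + tss - 1 if end > 0 else end + tss
            for b0, b1 in exon_spans:
                if a0 <= b1 and b0 <= a1:
                    raise ValueError(f"exon feature {name} overlaps another exon")
            exon_spans.append((a0, a1))

    # embed inverted-repeat arms at the ends of the named transposon fragments
    for feat in features:
        arm_len = cfg.get("inverted_repeats", {}).get(feat.name)
        if not arm_len:
            continue
        a0 = feat.start + tss - 1 if feat.start > 0 else feat.start + tss
        a1 = feat.end + tss - 1 if feat.end > 0 else feat.end + tss
        if a1 - a0 + 1 < 2 * arm_len + 2:
            raise ValueError(f"feature {feat.name} too short for {arm_len} bp inverted repeats")
        arm = _random_dna(rng, arm_len, float(cfg["gc_fraction"]))
        arr[a0 - 1 : a0 - 1 + arm_len] = arm
        rc = np.frombuffer(revcomp(arm.tobytes().decode()).encode(), dtype="S1")
        arr[a1 - arm_len : a1] = rc

    locus = ReferenceLocus(
        id=str(cfg["id"]),
        sequence=arr.tobytes().decode(),
        tss_array_pos=tss,
        features=features,
    )

    sources = [
        src if isinstance(src, SirnaSource) else SirnaSource(**src)
        for src in tcfg["sirna_sources"]
    ]
    for src in sources:
        a0 = locus.from_tss(src.start)
        a1 = locus.from_tss(src.end)
        if a1 - a0 + 1 < max(src.size_mix):
            raise ValueError(f"siRNA source {src.name} shorter than its longest size class")

    truth = SyntheticTruth(
        region_meth=tcfg["region_meth"],
        conversion_rate=float(tcfg["conversion_rate"]),
        seq_error_rate=float(tcfg["seq_error_rate"]),
        sirna_sources=sources,
        structural_fraction=float(tcfg["structural_fraction"]),
        noise_fraction=float(tcfg["noise_fraction"]),
        no_adapter_fraction=float(tcfg["no_adapter_fraction"]),
        expression_effect=dict(tcfg["expression_effect"]),
    )
    return locus, truth


# ---------------------------------------------------------------------------
# bisulfite clones


def simulate_clones(
    locus: ReferenceLocus,
    truth: SyntheticTruth,
    amplicon: tuple[int, int],
    strand: str,
    genotype: str,
    n_replicates: int,
    n_clones: int,
    seed: int,
) -> list[CloneSet]:
    """Simulate bisulfite-converted amplicon clones for one genotype.

    Each clone converts every cytosine site on the read strand independently:
    methylated sites (probability from the planted per-feature/per-context
    table) read C; unmethylated sites read T with probability
    ``conversion_rate`` and C otherwise.  Non-site bases acquire random
    substitutions at ``seq_error_rate``.
    """
    for per_ctx in truth.region_meth.values():
        for per_geno in per_ctx.values():
            if genotype not in per_geno:
                raise KeyError(f"unknown genotype {genotype!r}")
            break
        break

    rng = np.random.default_rng(seed)
    region = locus.region_sequence(*amplicon)
    read_seq = revcomp(region) if strand == "-" else region
    a0, a1 = locus.from_tss(amplicon[0]), locus.from_tss(amplicon[1])

    sites = enumerate_sites(locus, amplicon, strands=(strand,))
    # read-orientation index and planted probability per site
    site_index: list[tuple[int, float]] = []
    for site in sites:
        idx = (site.array_pos - a0) if strand == "+" else (a1 - site.array_pos)
        site_index.append((idx, truth.meth_probability(locus, site, genotype)))
    site_positions = np.array([i for i, _ in site_index], dtype=int)
    site_probs = np.array([p for _, p in site_index], dtype=float)
    is_site = np.zeros(len(read_seq), dtype=bool)
    is_site[site_positions] = True

    base_arr = np.frombuffer(read_seq.encode(), dtype="S1")
    clone_sets = []
    for rep in range(n_replicates):
        clones = []
        for _ in range(n_clones):
            clone = base_arr.copy()
            meth = rng.random(len(site_probs)) < site_probs
            converted = rng.random(len(site_probs)) < truth.conversion_rate
            to_t = site_positions[~meth & converted]
            clone[to_t] = b"T"
            # sequencing noise on non-site bases only
            err = (rng.random(len(clone)) < truth.seq_error_rate) & ~is_site
            idx_err = np.flatnonzero(err)
            if idx_err.size:
                subs = rng.choice(_BASES, size=idx_err.size)
                same = subs == clone[idx_err]
                while same.any():
                    subs[same] = rng.choice(_BASES, size=int(same.sum()))
                    same = subs == clone[idx_err]
                clone[idx_err] = subs
            clones.append(clone.tobytes().decode())
        clone_sets.append(
            CloneSet(
                genotype=genotype,
                replicate_id=f"{genotype}_rep{rep + 1}",
                amplicon=amplicon,
                strand=strand,
                clones=clones,
            )
        )
    return clone_sets


# ---------------------------------------------------------------------------
# small-RNA libraries


@dataclass
class SimulatedLibrary:
    """A simulated raw small-RNA library, collapsed to (read sequence -> count)."""

    id: str
    genotype: str
    replicate: str
    depth: int
    reads: Counter = field(default_factory=Counter)

    def to_fastq(self) -> str:
        chunks = []
        i = 0
        for seq in sorted(self.reads):
            for _ in range(self.reads[seq]):
                i += 1
                chunks.append(f"@{self.id}_read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        return "".join(chunks)


def make_structural_reference(seed: int = 0, n_records: int = 5) -> list[tuple[str, str]]:
    """Synthetic structural-RNA reference (tRNA/rRNA/sn/snoRNA-like records)."""
    rng = np.random.default_rng(seed)
    plans = [("rRNA_25S_frag", 400), ("rRNA_5.8S", 160), ("tRNA_Gly", 75),
             ("snoRNA_U3", 120), ("snRNA_U6", 105)]
    records = []
    for name, length in plans[:n_records]:
        records.append((name, _random_dna(rng, length, 0.5).tobytes().decode()))
    return records


def _emit_read(insert: str, adapter: str, read_length: int) -> str:
    return (insert + adapter)[:read_length]


def simulate_srna_libraries(
    locus: ReferenceLocus,
    truth: SyntheticTruth,
    libraries: Sequence[tuple[str, str, int]],  # (genotype, replicate, depth)
    adapter: str = TRUSEQ_ADAPTER,
    seed: int = 0,
    read_length: int = 36,
    structural_records: list[tuple[str, str]] | None = None,
) -> tuple[list[SimulatedLibrary], list[tuple[str, str]]]:
    """Simulate raw small-RNA libraries plus the structural reference.

    Read categories per library: locus-derived source reads (fractions set by
    each source's per-genotype weight), structural fragments, adapter-bearing
    unmatchable noise, and adapter-free junk.  Deterministic given ``seed``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    rng = np.random.default_rng(seed)
    if structural_records is None:
        structural_records = make_structural_reference(seed=int(rng.integers(2**31)))

    out: list[SimulatedLibrary] = []
    for genotype, replicate, depth in libraries:
        if depth <= 0:
            raise ValueError(f"library {genotype}/{replicate}: depth must be > 0")
        lib = SimulatedLibrary(
            id=f"{genotype}_{replicate}", genotype=genotype, replicate=replicate, depth=depth
        )
        weights = np.array([src.weights.get(genotype, 0.0) for src in truth.sirna_sources])
        if weights.sum() <= 0:
            raise ValueError(f"no siRNA source has positive weight for genotype {genotype!r}")
        source_total = 1.0 - truth.structural_fraction - truth.noise_fraction - truth.no_adapter_fraction
        probs = np.concatenate([
            weights / weights.sum() * source_total,
            [truth.structural_fraction, truth.noise_fraction, truth.no_adapter_fraction],
        ])
        counts = rng.multinomial(depth, probs)

        # locus-derived source reads, collapsed before string extraction
        for src, n in zip(truth.sirna_sources, counts[: len(truth.sirna_sources)]):
            if n == 0:
                continue
            a0, a1 = locus.from_tss(src.start), locus.from_tss(src.end)
            sizes = np.array(sorted(src.size_mix))
            size_p = np.array([src.size_mix[s] for s in sizes])
            lens = rng.choice(sizes, size=n, p=size_p)
            starts = np.empty(n, dtype=int)
            for length in np.unique(lens):
                mask = lens == length
                starts[mask] = rng.integers(a0, a1 - length + 2, size=int(mask.sum()))
            plus = rng.random(n) < src.plus_fraction
            rows = np.stack([starts, lens, plus.astype(int)], axis=1)
            uniq, cnt = np.unique(rows, axis=0, return_counts=True)
            for (start, length, is_plus), c in zip(uniq, cnt):
                insert = locus.sequence[start - 1 : start - 1 + length]
                if not is_plus:
                    insert = revcomp(insert)
                lib.reads[_emit_read(insert, adapter, read_length)] += int(c)

        # structural fragments
        n_struct = counts[len(truth.sirna_sources)]
        if n_struct:
            rec_idx = rng.integers(0, len(structural_records), size=n_struct)
            lens = rng.integers(18, 31, size=n_struct)
            starts = np.empty(n_struct, dtype=int)
            for i, (_, rec_seq) in enumerate(structural_records):
                mask = rec_idx == i
                if mask.any():
                    starts[mask] = rng.integers(
                        0, len(rec_seq) - 30 + 1, size=int(mask.sum())
                    )
            rows = np.stack([rec_idx, starts, lens], axis=1)
            uniq, cnt = np.unique(rows, axis=0, return_counts=True)
            for (ri, start, length), c in zip(uniq, cnt):
                insert = structural_records[ri][1][start : start + length]
                lib.reads[_emit_read(insert, adapter, read_length)] += int(c)

        # adapter-bearing unmatchable noise
        n_noise = counts[len(truth.sirna_sources) + 1]
        for length in rng.integers(18, 31, size=n_noise):
            insert = rng.choice(_BASES, size=length).tobytes().decode()
            lib.reads[_emit_read(insert, adapter, read_length)] += 1

        # adapter-free junk
        n_junk = counts[len(truth.sirna_sources) + 2]
        for _ in range(n_junk):
            lib.reads[rng.choice(_BASES, size=read_length).tobytes().decode()] += 1

        out.append(lib)
    return out, structural_records


# ---------------------------------------------------------------------------
# Ct tables


def simulate_expression_ct(
    truth: SyntheticTruth,
    seed: int,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_sd: float = 0.2,
    control_ct: float = 20.0,
    base_delta_ct: float = 8.0,
) -> pd.DataFrame:
    """Ct table for relative-expression analysis from the planted effects.

    For each genotype the true ΔCt is ``base_delta_ct - log2(effect)``;
    technical replicates add Gaussian noise on the Ct scale.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, effect in truth.expression_effect.items():
        if effect <= 0:
            raise ValueError(f"expression effect for {genotype!r} must be > 0")
        for bio in range(1, n_bio + 1):
            ctrl_true = control_ct + rng.normal(0.0, 0.1)
            tgt_true = ctrl_true + base_delta_ct - np.log2(effect)
            for tech in range(1, n_tech + 1):
                rows.append((genotype, f"bio{bio}", "gene_of_interest", "expression",
                             tgt_true + rng.normal(0.0, ct_sd), tech))
                rows.append((genotype, f"bio{bio}", "endogenous_control", "expression",
                             ctrl_true + rng.normal(0.0, ct_sd), tech))
    return pd.DataFrame(
        rows, columns=["sample", "replicate", "target", "assay", "ct", "tech_rep"]
    )


def simulate_chip_ct(
    true_percent: Mapping[str, float],
    seed: int,
    input_fraction: float = 0.01,
    no_antibody_percent: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_sd: float = 0.15,
    input_ct: float = 28.0,
) -> pd.DataFrame:
    """ChIP-qPCR Ct table with planted percent-of-input per sample."""
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    dilution = np.log2(1.0 / input_fraction)
    rows = []
    for sample, pct in true_percent.items():
        if pct <= 0:
            raise ValueError(f"true percent for {sample!r} must be > 0")
        for bio in range(1, n_bio + 1):
            ct_in = input_ct + rng.normal(0.0, 0.1)
            adj = ct_in - dilution
            ct_chip_true = adj - np.log2(pct / 100.0)
            ct_noab_true = adj - np.log2(no_antibody_percent / 100.0)
            for tech in range(1, n_tech + 1):
                rows.append((sample, f"bio{bio}", "locus_region", "input",
                             ct_in + rng.normal(0.0, ct_sd), tech))
                rows.append((sample, f"bio{bio}", "locus_region", "chip",
                             ct_chip_true + rng.normal(0.0, ct_sd), tech))
                rows.append((sample, f"bio{bio}", "locus_region", "no_antibody",
                             ct_noab_true + rng.normal(0.0, ct_sd), tech))
    return pd.DataFrame(
        rows, columns=["sample", "replicate", "target", "assay", "ct", "tech_rep"]
    )


# ---------------------------------------------------------------------------
# text-format writers


def locus_to_fasta(locus: ReferenceLocus, width: int = 70) -> str:
    lines = [f">{locus.id}"]
    for i in range(0, len(locus.sequence), width):
        lines.append(locus.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def features_to_bed(locus: ReferenceLocus) -> str:
    """BED6 (0-based half-open) of the locus features, in array coordinates."""
    lines = []
    for feat in locus.features:
        a0 = locus.from_tss(feat.start)
        a1 = locus.from_tss(feat.end)
        lines.append(f"{locus.id}\t{a0 - 1}\t{a1}\t{feat.name}\t0\t{feat.strand}")
    return "\n".join(lines) + "\n"


def clones_to_fasta(clone_set: CloneSet) -> str:
    meta = (
        f"genotype={clone_set.genotype} replicate={clone_set.replicate_id} "
        f"amplicon={clone_set.amplicon[0]}:{clone_set.amplicon[1]} strand={clone_set.strand}"
    )
    lines = []
    for i, clone in enumerate(clone_set.clones, 1):
        lines.append(f">clone_{i:03d} {meta}")
        lines.append(clone)
    return "\n".join(lines) + "\n"


def structural_to_fasta(records: Iterable[tuple[str, str]]) -> str:
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.append(seq)
    return "\n".join(lines) + "\n"
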