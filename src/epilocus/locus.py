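"""Reference locus representation and cytosine context classification.

A single genomic locus (here, a multicopy maize gene such as *p1*) is held as
an uppercase DNA string together with the array position of the transcription
start site (TSS) and a set of annotated features (exons, intron sub-regions,
enhancers, transposon fragments).  All reported coordinates are TSS-relative
and skip zero: the TSS itself is +1 and the base immediately upstream is -1,
the convention used throughout plant locus studies.  Internally everything is
1-based array coordinates; conversion happens only at I/O boundaries.

Cytosine methylation contexts follow the standard plant trichotomy:

* CG   — the next base (3' on the cytosine's strand) is G;
* CHG  — C, then H, then G, with H in {A, C, T};
* CHH  — C followed by two H bases.

Sites whose defining window runs off the sequence or contains an N are
classified UNKNOWN and excluded from downstream tallies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Context",
    "FeatureClass",
    "Feature",
    "CytosineSite",
    "ReferenceLocus",
    "to_tss_coord",
    "from_tss_coord",
    "classify_context",
    "enumerate_sites",
    "parse_locus",
    "revcomp",
    "sites_to_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
H_BASES = frozenset("ACT")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Context(str, Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNKNOWN = "UNKNOWN"


class FeatureClass(str, Enum):
    EXON = "exon"
    INTRON_SUBREGION = "intron_subregion"
    ENHANCER = "enhancer"
    TRANSPOSON = "transposon"
    REPEAT = "repeat"
    OTHER = "other"


# keyword → class used when a BED name carries no explicit class
_CLASS_KEYWORDS = (
    ("exon", FeatureClass.EXON),
    ("int2", FeatureClass.INTRON_SUBREGION),
    ("intron", FeatureClass.INTRON_SUBREGION),
    ("enhancer", FeatureClass.ENHANCER),
    ("mule", FeatureClass.TRANSPOSON),
    ("stowaway", FeatureClass.TRANSPOSON),
    ("tourist", FeatureClass.TRANSPOSON),
    ("hat", FeatureClass.TRANSPOSON),
    ("harbinger", FeatureClass.TRANSPOSON),
    ("repeat", FeatureClass.REPEAT),
)


def infer_feature_class(name: str) -> FeatureClass:
    low = name.lower()
    for key, klass in _CLASS_KEYWORDS:
        if key in low:
            return klass
    return FeatureClass.OTHER


@dataclass(frozen=True)
class Feature:
    """An annotated interval in inclusive TSS-relative coordinates."""

    name: str
    klass: FeatureClass
    start: int  # TSS-relative, inclusive, never 0
    end: int    # TSS-relative, inclusive, never 0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise ValueError(f"feature {self.name}: TSS-relative coordinate 0 is undefined")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class CytosineSite:
    array_pos: int  # 1-based position in the sequence
    tss_pos: int    # TSS-relative, never 0
    strand: str     # '+' or '-'
    context: Context


@dataclass
class ReferenceLocus:
    id: str
    sequence: str
    tss_array_pos: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("locus sequence is empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"locus sequence contains non-DNA characters: {sorted(bad)}")
        if not 1 <= self.tss_array_pos <= len(self.sequence):
            raise ValueError("tss_array_pos outside sequence")
        for feat in self.features:
            a0 = self.from_tss(feat.start)
            a1 = self.from_tss(feat.end)
            if a0 > a1:
                raise ValueError(f"feature {feat.name}: start after end in array coordinates")
            if a0 < 1 or a1 > len(self.sequence):
                raise ValueError(f"feature {feat.name}: interval outside locus")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_tss(self, array_pos: int) -> int:
        return to_tss_coord(array_pos, self.tss_array_pos)

    def from_tss(self, tss_pos: int) -> int:
        return from_tss_coord(tss_pos, self.tss_array_pos)

    def feature_by_name(self, name: str) -> Feature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise KeyError(name)

    def features_overlapping(self, start: int, end: int) -> list[Feature]:
        """Features whose inclusive TSS interval overlaps [start, end] (TSS-relative)."""
        a0, a1 = self.from_tss(start), self.from_tss(end)
        out = []
        for feat in self.features:
            f0, f1 = self.from_tss(feat.start), self.from_tss(feat.end)
            if f0 <= a1 and a0 <= f1:
                out.append(feat)
        return out

    def region_sequence(self, start: int, end: int) -> str:
        """Array-orientation sequence of an inclusive TSS-relative interval."""
        a0, a1 = self.from_tss(start), self.from_tss(end)
        if a0 > a1:
            raise ValueError("region start after end")
        if a0 < 1 or a1 > len(self.sequence):
            raise ValueError("region outside locus")
        return self.sequence[a0 - 1 : a1]


def to_tss_coord(array_pos: int, tss_array_pos: int) -> int:
    """Map a 1-based array position to the no-zero TSS-relative coordinate.

    The TSS maps to +1; the position immediately upstream maps to -1.
    """
    if array_pos >= tss_array_pos:
        return array_pos - tss_array_pos + 1
    return array_pos - tss_array_pos


def from_tss_coord(tss_pos: int, tss_array_pos: int) -> int:
    """Inverse of :func:`to_tss_coord`; rejects the undefined coordinate 0."""
    if tss_pos == 0:
        raise ValueError("TSS-relative coordinate 0 is undefined (-1 abuts +1)")
    if tss_pos > 0:
        return tss_pos + tss_array_pos - 1
    return tss_pos + tss_array_pos


def classify_context(sequence: str, array_pos: int, strand: str) -> Context:
    """Classify the methylation context of a cytosine site.

    ``array_pos`` is 1-based; on '+' the reference base there must be C, on
    '-' it must be G (the cytosine lives on the bottom strand and its 3'
    neighbours lie at decreasing array positions).
    """
    i = array_pos - 1
    if strand == "+":
        if sequence[i] != "C":
            raise ValueError(f"base at {array_pos} on '+' is {sequence[i]!r}, not C")
        nxt = sequence[i + 1] if i + 1 < len(sequence) else None
        nxt2 = sequence[i + 2] if i + 2 < len(sequence) else None
    elif strand == "-":
        if sequence[i] != "G":
            raise ValueError(f"base at {array_pos} on '-' is {sequence[i]!r}, not G")
        # complement so the rules below read in the bottom strand's 5'->3' sense
        nxt = sequence[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else None
        nxt2 = sequence[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")

    if nxt is None or nxt == "N":
        return Context.UNKNOWN
    if nxt == "G":
        return Context.CG
    if nxt not in H_BASES:
        return Context.UNKNOWN
    if nxt2 is None or nxt2 == "N":
        return Context.UNKNOWN
    if nxt2 == "G":
        return Context.CHG
    if nxt2 in H_BASES:
        return Context.CHH
    return Context.UNKNOWN


def enumerate_sites(
    locus: ReferenceLocus,
    region: tuple[int, int],
    strands: Iterable[str] = ("+", "-"),
) -> list[CytosineSite]:
    """All cytosine sites in an inclusive TSS-relative region, ordered by array position."""
    strands = set(strands)
    bad = strands - {"+", "-"}
    if bad:
        raise ValueError(f"bad strands {sorted(bad)}")
    a0 = locus.from_tss(region[0])
    a1 = locus.from_tss(region[1])
    if a0 > a1:
        return []
    if a0 < 1 or a1 > len(locus):
        raise ValueError("region outside locus")
    sites: list[CytosineSite] = []
    seq = locus.sequence
    for pos in range(a0, a1 + 1):
        base = seq[pos - 1]
        if base == "C" and "+" in strands:
            sites.append(
                CytosineSite(pos, locus.to_tss(pos), "+", classify_context(seq, pos, "+"))
            )
        elif base == "G" and "-" in strands:
            sites.append(
                CytosineSite(pos, locus.to_tss(pos), "-", classify_context(seq, pos, "-"))
            )
    return sites


def parse_locus(
    fasta_text: str,
    bed_text: str,
    tss_array_pos: int,
    class_map: dict[str, FeatureClass] | None = None,
) -> ReferenceLocus:
    """Build a :class:`ReferenceLocus` from single-record FASTA and BED6 text.

    BED intervals are standard 0-based half-open and are converted to
    inclusive TSS-relative feature coordinates.  Feature classes come from
    ``class_map`` (name → class) when given, else from name keywords.
    """
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()

    features: list[Feature] = []
    for line in bed_text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"BED line has fewer than 4 fields: {line!r}")
        start0, end0, name = int(parts[1]), int(parts[2]), parts[3]
        strand = parts[5] if len(parts) >= 6 else "."
        if start0 < 0 or end0 > len(seq) or start0 >= end0:
            raise ValueError(
                f"feature {name}: BED interval [{start0}, {end0}) outside sequence of length {len(seq)}"
            )
        klass = (class_map or {}).get(name) or infer_feature_class(name)
        features.append(
            Feature(
                name=name,
                klass=klass,
                start=to_tss_coord(start0 + 1, tss_array_pos),
                end=to_tss_coord(end0, tss_array_pos),
                strand=strand,
            )
        )
    return ReferenceLocus(id=rec.id, sequence=seq, tss_array_pos=tss_array_pos, features=features)


def sites_to_tsv(sites: Sequence[CytosineSite]) -> str:
    lines = ["array_pos\ttss_pos\tstrand\tcontext"]
    for s in sites:
        lines.append(f"{s.array_pos}\t{s.tss_pos}\t{s.strand}\t{s.context.value}")
    return "\n".join(lines) + "\n"
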