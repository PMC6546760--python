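"""Transcript annotation, principal-isoform selection and mutation mapping.

Genomic inputs follow the VCF convention (1-based positions); all internal
intervals are 0-based half-open, and positions on the mature (spliced)
transcript are 0-based.  Substitutions are classified into the standard
strand-collapsed trinucleotide partition: 6 substitution types x 16 flank
combinations = 96 mutation classes, and 2 pyrimidine centers x 16 flanks =
32 context classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: the six pyrimidine-centered substitution types, in the conventional order
SUBSTITUTION_TYPES = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)
_SUBST_INDEX = {s: i for i, s in enumerate(SUBSTITUTION_TYPES)}

N_SUBSTITUTION_CLASSES = 96
N_CONTEXT_CLASSES = 32

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGION_LNCRNA = "lncRNA"
REGION_INTRON = "intron"

#: element classes eligible for enrichment testing (coding mutations are
#: excluded because their structural effect is confounded by protein-level
#: consequences)
NONCODING_REGIONS = (REGION_5UTR, REGION_3UTR, REGION_LNCRNA)


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide variant in genomic coordinates (1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = "."
    cohort: str = "unknown"

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise AnnotationError(
                f"alleles must be single canonical bases, got {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise AnnotationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise AnnotationError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}:{self.sample_id}"


@dataclass
class Transcript:
    """An annotated spliced transcript.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic
    coordinate; ``regions`` (optional) sub-annotates the mature coordinate
    axis into 5UTR/CDS/3UTR intervals for protein-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list  # [(start, end), ...] 0-based half-open, sorted
    appris_rank: Optional[int] = None
    has_ccds: bool = False
    transcript_level: Optional[int] = None
    regions: Optional[dict] = None  # {region_name: [(start, end), ...]} mature coords

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise AnnotationError(f"empty exon [{s},{e}) in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons
        if self.regions:
            for name, ivals in self.regions.items():
                for (s, e) in ivals:
                    if not (0 <= s <= e <= self.mature_length):
                        raise AnnotationError(
                            f"region {name} [{s},{e}) outside mature transcript "
                            f"{self.transcript_id}"
                        )

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_to_mature(self, g: int) -> Optional[int]:
        """0-based genomic position -> 0-based mature position, or None."""
        off = 0
        for s, e in self.exons:
            if s <= g < e:
                k = off + (g - s)
                return k if self.strand == "+" else self.mature_length - 1 - k
            off += e - s
        return None

    def mature_to_genomic(self, k: int) -> int:
        if not (0 <= k < self.mature_length):
            raise AnnotationError(f"mature position {k} outside transcript")
        off = k if self.strand == "+" else self.mature_length - 1 - k
        for s, e in self.exons:
            if off < e - s:
                return s + off
            off -= e - s
        raise AssertionError("unreachable")

    def region_at(self, k: int) -> Optional[str]:
        """Region label of a mature position."""
        if self.biotype == "lncRNA":
            return REGION_LNCRNA
        if self.regions:
            for name, ivals in self.regions.items():
                for s, e in ivals:
                    if s <= k < e:
                        return name
        return None

    def introns(self) -> list:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class MappedMutation:
    """An SNV projected onto a mature transcript.

    ``k`` is None for intronic mutations (which only feed the neutral
    profile); alleles and trinucleotide context are on the transcript strand.
    """

    record: MutationRecord
    transcript_id: str
    k: Optional[int]
    ref_t: str
    alt_t: str
    tri_context: Optional[str]
    region: Optional[str]
    subst_class96: Optional[int]
    tri_class32: Optional[int]


# ---------------------------------------------------------------------------
# substitution classification


def classify_substitution(tri_context: str, ref_t: str, alt_t: str):
    """Classify a substitution into (96-class, 32-class) indices.

    Purine-centered contexts are reverse-complemented first so every class
    has a pyrimidine (C/T) center; a substitution and its reverse complement
    therefore classify identically.  Returns None when the context contains
    a non-ACGT base (the mutation is excluded, not an error).
    """
    if len(tri_context) != 3:
        raise AnnotationError(f"trinucleotide context must have length 3: {tri_context!r}")
    if tri_context[1] != ref_t:
        raise AnnotationError(
            f"context center {tri_context[1]!r} does not match ref allele {ref_t!r}"
        )
    if any(b not in BASES for b in tri_context) or alt_t not in BASES:
        return None
    if ref_t == alt_t:
        raise AnnotationError("ref == alt is not a substitution")
    if ref_t in "AG":  # strand collapse
        tri_context = reverse_complement(tri_context)
        ref_t = complement(ref_t)
        alt_t = complement(alt_t)
    si = _SUBST_INDEX[(ref_t, alt_t)]
    f5 = BASES.index(tri_context[0])
    f3 = BASES.index(tri_context[2])
    c96 = si * 16 + f5 * 4 + f3
    c32 = (0 if ref_t == "C" else 1) * 16 + f5 * 4 + f3
    return c96, c32


def context_class_of(c96: int) -> int:
    """32-class trinucleotide context of a 96-class substitution."""
    si, flanks = divmod(c96, 16)
    return (0 if si < 3 else 1) * 16 + flanks


def class96_alleles(c96: int) -> tuple:
    """(collapsed ref, collapsed alt) of a 96-class index."""
    return SUBSTITUTION_TYPES[c96 // 16]


def class96_label(c96: int) -> str:
    si, flanks = divmod(c96, 16)
    ref, alt = SUBSTITUTION_TYPES[si]
    return f"{BASES[flanks // 4]}[{ref}>{alt}]{BASES[flanks % 4]}"


def class32_label(c32: int) -> str:
    center, flanks = divmod(c32, 16)
    return f"{BASES[flanks // 4]}{'CT'[center]}{BASES[flanks % 4]}"


def classify_position(seq: str, k: int) -> Optional[int]:
    """32-class of position ``k`` of ``seq`` (None at edges or near N)."""
    if k < 1 or k > len(seq) - 2:
        return None
    tri = seq[k - 1:k + 2]
    if any(b not in BASES for b in tri):
        return None
    if tri[1] in "AG":
        tri = reverse_complement(tri)
    return (0 if tri[1] == "C" else 1) * 16 + BASES.index(tri[0]) * 4 + BASES.index(tri[2])


# ---------------------------------------------------------------------------
# principal transcript selection


def select_principal_transcript(transcripts: Sequence[Transcript]) -> Transcript:
    """Pick one principal isoform per gene.

    Priority: lower APPRIS rank (missing ranks last) > CCDS membership >
    lower transcript level (missing last) > greater mature length; a final
    deterministic tie-break on the transcript id.
    """
    ts = list(transcripts)
    if not ts:
        raise AnnotationError("no transcripts")
    gene_ids = {t.gene_id for t in ts}
    if len(gene_ids) > 1:
        raise AnnotationError(f"transcripts from multiple genes: {sorted(gene_ids)}")

    def key(t: Transcript):
        return (
            t.appris_rank if t.appris_rank is not None else 6,
            0 if t.has_ccds else 1,
            t.transcript_level if t.transcript_level is not None else 99,
            -t.mature_length,
            t.transcript_id,
        )

    return min(ts, key=key)


# ---------------------------------------------------------------------------
# sequence extraction and mutation mapping


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Uppercase genome slice [start, end); works for pyfaidx.Fasta or dict."""
    try:
        chrom_seq = genome[chrom]
    except KeyError as exc:
        raise AnnotationError(f"chromosome {chrom!r} not in genome") from exc
    if start < 0 or end > len(chrom_seq):
        raise AnnotationError(
            f"interval [{start},{end}) outside chromosome {chrom} (len {len(chrom_seq)})"
        )
    return str(chrom_seq[start:end]).upper()


def extract_mature_sequence(transcript: Transcript, genome) -> str:
    """Spliced, strand-corrected mature sequence (DNA alphabet, uppercase)."""
    parts = [_fetch(genome, transcript.chrom, s, e) for s, e in transcript.exons]
    seq = "".join(parts)
    bad = set(seq) - set(BASES + "N")
    if bad:
        raise AnnotationError(f"non-ACGTN bases {sorted(bad)} in {transcript.transcript_id}")
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def map_mutation(
    record: MutationRecord,
    transcript: Transcript,
    genome,
    mature_seq: Optional[str] = None,
) -> Optional[MappedMutation]:
    """Project an SNV onto a transcript.

    Returns a MappedMutation with mature coordinate ``k`` for exonic hits,
    an intronic MappedMutation (``k`` is None) between the first and last
    exon, and None outside the transcript span.
    """
    if record.chrom != transcript.chrom:
        return None
    g = record.pos - 1
    lo, hi = transcript.span
    if not (lo <= g < hi):
        return None
    genome_base = _fetch(genome, record.chrom, g, g + 1)
    if genome_base != record.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome {genome_base} vs record {record.ref}"
        )
    minus = transcript.strand == "-"
    ref_t = complement(record.ref) if minus else record.ref
    alt_t = complement(record.alt) if minus else record.alt

    k = transcript.genomic_to_mature(g)
    if k is None:  # intronic
        tri = _fetch(genome, record.chrom, max(0, g - 1), g + 2)
        if len(tri) != 3:
            tri = None
        elif minus:
            tri = reverse_complement(tri)
        classes = classify_substitution(tri, ref_t, alt_t) if tri else None
        c96, c32 = classes if classes else (None, None)
        return MappedMutation(
            record, transcript.transcript_id, None, ref_t, alt_t, tri,
            REGION_INTRON, c96, c32,
        )

    if mature_seq is None:
        mature_seq = extract_mature_sequence(transcript, genome)
    if mature_seq[k] != ref_t:
        raise ReferenceMismatchError(
            f"mature base {mature_seq[k]} at k={k} does not match ref_t {ref_t} "
            f"({transcript.transcript_id})"
        )
    tri = mature_seq[k - 1:k + 2] if 1 <= k <= len(mature_seq) - 2 else None
    classes = classify_substitution(tri, ref_t, alt_t) if tri else None
    c96, c32 = classes if classes else (None, None)
    return MappedMutation(
        record, transcript.transcript_id, k, ref_t, alt_t, tri,
        transcript.region_at(k), c96, c32,
    )


def noncoding_elements(t: Transcript, mature_length: Optional[int] = None) -> list:
    """Noncoding elements of a transcript as (element_id, class, positions).

    lncRNAs contribute one whole-transcript element; protein-coding
    transcripts contribute their UTRs (coding positions are excluded from
    the enrichment analysis).  Positions are mature coordinates restricted
    to [1, L-2] so every position has a trinucleotide context.
    """
    L = mature_length if mature_length is not None else t.mature_length
    out = []
    if t.biotype == "lncRNA":
        out.append((t.gene_name, REGION_LNCRNA, list(range(1, L - 1))))
    elif t.biotype == "protein_coding" and t.regions:
        for region in (REGION_5UTR, REGION_3UTR):
            pos = []
            for s, e in t.regions.get(region, []):
                pos.extend(range(max(1, s), min(e, L - 1)))
            if pos:
                out.append((f"{t.gene_name}:{region}", region, pos))
    return out


# ---------------------------------------------------------------------------
# blacklist filtering


def read_bed(path) -> list:
    """Read (chrom, start, end) tuples from a BED file (extra columns ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows


def filter_blacklist(mutations: Sequence[MutationRecord], blacklist) -> list:
    """Drop mutations whose 0-based position falls inside a blacklist interval."""
    if isinstance(blacklist, (str, Path)):
        blacklist = read_bed(blacklist)
    intervals = list(blacklist)
    if not intervals:
        return list(mutations)
    from intervaltree import IntervalTree

    trees = {}
    for chrom, start, end in intervals:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for m in mutations:
        tree = trees.get(m.chrom)
        if tree is None or not tree.overlaps_point(m.pos - 1):
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# file readers


_APPRIS_RE = re.compile(r"appris_principal(?:_(\d))?$")


def _parse_transcript_attrs(attrs: Mapping) -> dict:
    tags = list(attrs.get("tag", []))
    appris = None
    for tag in tags:
        m = _APPRIS_RE.match(tag)
        if m:
            rank = int(m.group(1)) if m.group(1) else 1
            appris = rank if appris is None else min(appris, rank)
    has_ccds = "ccdsid" in attrs or "ccds_id" in attrs or any(
        t == "CCDS" or t.startswith("CCDS") for t in tags
    )
    level = None
    for key in ("level", "transcript_support_level"):
        raw = attrs.get(key, [None])[0]
        if raw is not None and str(raw).strip().isdigit():
            level = int(str(raw).strip())
            break
    return {"appris_rank": appris, "has_ccds": has_ccds, "transcript_level": level}


def load_annotation(gtf_path) -> dict:
    """Read a GENCODE-style GTF into ``{gene_id: [Transcript, ...]}``.

    Protein-coding transcripts get a mature-coordinate 5UTR/CDS/3UTR
    sub-annotation derived from their CDS features.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True, keep_order=True,
    )
    genes: dict = {}
    for feat in db.features_of_type("transcript"):
        attrs = feat.attributes
        gene_id = attrs["gene_id"][0]
        biotype_raw = attrs.get("gene_type", ["other"])[0]
        if biotype_raw in ("lncRNA", "lincRNA", "antisense"):
            biotype = "lncRNA"
        elif biotype_raw == "protein_coding":
            biotype = "protein_coding"
        else:
            biotype = "other"
        exons = [
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        t = Transcript(
            transcript_id=attrs["transcript_id"][0],
            gene_id=gene_id,
            gene_name=attrs.get("gene_name", [gene_id])[0],
            biotype=biotype,
            chrom=feat.seqid,
            strand=feat.strand,
            exons=exons,
            **_parse_transcript_attrs(attrs),
        )
        cds = [
            (c.start - 1, c.end)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        ]
        if cds and biotype == "protein_coding":
            t.regions = _regions_from_cds(t, cds)
        genes.setdefault(gene_id, []).append(t)
    return genes


def _regions_from_cds(t: Transcript, cds_intervals: list) -> dict:
    ks = []
    for s, e in cds_intervals:
        for g in (s, e - 1):
            k = t.genomic_to_mature(g)
            if k is None:
                raise AnnotationError(
                    f"CDS boundary {g} not exonic in {t.transcript_id}"
                )
            ks.append(k)
    lo, hi = min(ks), max(ks) + 1
    regions = {}
    if lo > 0:
        regions[REGION_5UTR] = [(0, lo)]
    regions[REGION_CDS] = [(lo, hi)]
    if hi < t.mature_length:
        regions[REGION_3UTR] = [(hi, t.mature_length)]
    return regions


def read_mutations(path, cohort: str = "unknown") -> list:
    """Read SNVs from a 5-column TSV (chrom pos ref alt sample) or a VCF.

    Indels are dropped; multi-allelic VCF records are split into biallelic
    SNVs.
    """
    path = Path(path)
    records: list = []
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.ref is None or len(rec.ref) != 1 or rec.ref not in BASES:
                    continue
                sample = rec.info.get("SAMPLE", rec.id or ".")
                if isinstance(sample, tuple):
                    sample = sample[0]
                for alt in rec.alts or ():
                    if len(alt) != 1 or alt not in BASES or alt == rec.ref:
                        continue
                    records.append(
                        MutationRecord(rec.chrom, rec.pos, rec.ref, alt,
                                       str(sample), cohort)
                    )
    else:
        df = pd.read_table(
            path, comment="#", header=None,
            names=["chrom", "pos", "ref", "alt", "sample_id"],
            dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "sample_id": str},
        )
        for row in df.itertuples(index=False):
            ref, alt = row.ref.upper(), row.alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                continue
            if ref == alt:
                continue
            records.append(
                MutationRecord(row.chrom, int(row.pos), ref, alt,
                               str(row.sample_id), cohort)
            )
    return records
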