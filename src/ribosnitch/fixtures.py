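"""Synthetic fixture generation: genomes, annotation, benchmarks, cohorts.

Everything the pipeline consumes can be generated from a seeded
:class:`FixtureSpec`: a toy genome with multi-exon, mixed-strand genes in
GENCODE-style GTF; hairpin SNV benchmarks; and somatic/germline mutation
cohorts drawn from a chosen 96-class neutral profile with optional planted
riboSNitch-enriched or -depleted elements.

Two deliberate constructions shape the cohorts:

* Transcripts come in two structural classes.  Unplanted transcripts are
  structurally quiet (A/C-rich, near pairing-free), so their mutations
  score low.  Transcripts carrying planted elements embed fixed marginal
  GC hairpins whose interior stem breaks score far above the quiet
  background: one hairpin for enriched elements (rare hot sites that
  oversampling can find) and three for depleted elements, because an
  observed riboSNitch *deficit* is only testable when the neutral
  expectation on that transcript is high.  Using the same fixed stems
  everywhere keeps hot-site scores comparable across transcripts, so
  cohort-level tail thresholds interleave elements instead of collapsing
  onto one of them.
* Planting is rejection sampling on the pipeline's own scorer: candidate
  mutations are oversampled, scored, and the top (enriched) or bottom
  (depleted) ranks kept.  This is circular by design - it tests recovery
  of a planted signal, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .annotation import (
    BASES,
    N_SUBSTITUTION_CLASSES,
    Transcript,
    classify_position,
    complement,
    context_class_of,
    load_annotation,
    noncoding_elements,
    reverse_complement,
    select_principal_transcript,
    extract_mature_sequence,
)
from .benchmark import BenchmarkPair, LABEL_POS, LABEL_NEG
from .folding import FoldConfig, mutate_sequence, pairedness_profile
from .neutral import (
    MutationProfile96,
    recalibrate,
    sample_mutations,
    transcript_composition,
)
from .structure_diff import score_profiles


class FixtureError(ValueError):
    pass


def default_profile() -> np.ndarray:
    """A skewed but dense 96-class frequency profile.

    All classes carry mass; transitions are favoured and C>T in a CpG
    context strongly so, echoing the dominance of spontaneous-deamination
    signatures in real somatic spectra.
    """
    w = np.ones(N_SUBSTITUTION_CLASSES)
    for c in range(N_SUBSTITUTION_CLASSES):
        si, flanks = divmod(c, 16)
        if si == 2:  # C>T
            w[c] *= 3.0
            if flanks % 4 == 2:  # 3' G: CpG transition
                w[c] *= 5.0
        elif si == 4:  # T>C
            w[c] *= 2.0
    return w / w.sum()


@dataclass(frozen=True)
class PlantedElement:
    gene_name: str
    effect: str  # 'enriched' | 'depleted'
    fold_effect: float
    n_mutations: int

    def __post_init__(self):
        if self.effect == "enriched" and self.fold_effect <= 1:
            raise FixtureError("enriched elements need fold_effect > 1")
        if self.effect == "depleted" and self.fold_effect >= 1:
            raise FixtureError("depleted elements need fold_effect < 1")
        if self.effect not in ("enriched", "depleted"):
            raise FixtureError(f"unknown effect {self.effect!r}")


@dataclass
class FixtureSpec:
    """Fully determines all generated fixtures given its seed."""

    seed: int = 0
    n_genes: int = 12
    transcript_length_range: tuple = (72, 100)
    intron_length_range: tuple = (60, 120)
    strand_minus_fraction: float = 0.5
    profile_96: Optional[np.ndarray] = None
    mutations_per_element: int = 40
    n_intronic_mutations: int = 4000
    planted_elements: Optional[list] = None
    #: folding parameters matched to the generated transcripts: the pair
    #: span is capped so structural elements farther apart than the span
    #: cannot interact (hot-site scores stay context-free and comparable
    #: across transcripts)
    fold_config: FoldConfig = field(default_factory=lambda: FoldConfig(max_span_L=30))
    #: scoring half-window used both for planting selection and intended
    #: for the downstream analysis; small enough that it fits inside the
    #: generated transcripts
    diff_window: int = 15

    def __post_init__(self):
        if self.n_genes < 1:
            raise FixtureError("need at least one gene")
        lo, hi = self.transcript_length_range
        if not (30 <= lo <= hi):
            raise FixtureError("transcript lengths must be >= 30 nt")
        if self.profile_96 is None:
            self.profile_96 = default_profile()
        self.profile_96 = np.asarray(self.profile_96, dtype=float)
        self.profile_96 = self.profile_96 / self.profile_96.sum()
        if self.planted_elements is None:
            self.planted_elements = self._default_planted()
        names = {g for g, _ in self.gene_table()}
        for p in self.planted_elements:
            if p.gene_name not in names:
                raise FixtureError(f"planted gene {p.gene_name!r} not in gene table")

    def _default_planted(self) -> list:
        if self.n_genes < 6:
            return []
        # depleted elements carry more mutations: an observed *deficit* is
        # only significant when the expected count it falls short of is
        # itself large
        return [
            PlantedElement("LNC1", "enriched", 10.0, 24),
            PlantedElement("LNC2", "enriched", 10.0, 24),
            PlantedElement("LNC3", "depleted", 0.1, 144),
            PlantedElement("LNC4", "depleted", 0.1, 144),
        ]

    def hairpins_for(self, gene_name: str) -> int:
        """Hairpin count of a gene: 3 for depleted, 1 for enriched, else 0."""
        for p in self.planted_elements:
            if p.gene_name == gene_name:
                return 3 if p.effect == "depleted" else 1
        return 0

    def gene_table(self) -> list:
        """[(gene_name, biotype), ...]; two thirds lncRNA, one third coding."""
        n_lnc = max(1, math.ceil(self.n_genes * 2 / 3))
        table = [(f"LNC{i + 1}", "lncRNA") for i in range(n_lnc)]
        table += [(f"PCG{i + 1}", "protein_coding") for i in range(self.n_genes - n_lnc)]
        return table


# ---------------------------------------------------------------------------
# sequence builders


def _background(rng: np.random.Generator, n: int) -> str:
    """Structurally quiet background: mostly A/C, very sparse G/T."""
    return "".join(rng.choice(list(BASES), size=n, p=[0.83, 0.13, 0.02, 0.02]))


#: the fixed reference hairpin embedded in planted transcripts: an
#: aperiodic GC stem with an unpaired all-A loop
_STEM = "GCCGCGGC"
_HAIRPIN = _STEM + "AAAA" + reverse_complement(_STEM)

#: gap kept between hairpins, at least the study's maximal pair span, so
#: neighbouring hairpins cannot heal each other by cross-pairing
_HAIRPIN_GAP = 30


def _fixed_pad(length: int, salt: int) -> str:
    """Deterministic quiet pad (A/C) shared by all planted transcripts.

    Planted transcripts are built from constant sequences: identical
    local context makes hot-site (stem-break) scores identical across
    transcripts, so cohort tail thresholds split tail slots between
    planted elements instead of collapsing onto whichever transcript
    happened to score marginally higher.
    """
    rng = np.random.default_rng(987_654 + salt)
    return "".join(rng.choice(["A", "C"], size=length, p=[0.8, 0.2]))


def _planted_sequence(n_hairpins: int) -> str:
    """Constant mature sequence with ``n_hairpins`` embedded hairpins.

    Single-hairpin (enriched) transcripts get long pads: diluting their
    hot-site share keeps the pooled simulated tail from being absorbed by
    the enriched transcripts, which would starve the depleted elements'
    expectation.
    """
    edge, gap = 50 if n_hairpins == 1 else 25, _HAIRPIN_GAP
    parts = [_fixed_pad(edge, 0)]
    for i in range(n_hairpins):
        if i:
            parts.append(_fixed_pad(gap, i))
        parts.append(_HAIRPIN)
    parts.append(_fixed_pad(edge, 9))
    return "".join(parts)


def _transcript_sequence(rng: np.random.Generator, n: int,
                         n_hairpins: int = 0) -> str:
    """Quiet random background, or the constant planted design."""
    if n_hairpins == 0:
        return _background(rng, n)
    return _planted_sequence(n_hairpins)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# genome + annotation


def _split_exon_lengths(rng, total: int, n_exons: int, min_len: int = 20) -> list:
    if total < n_exons * min_len:
        return [total]
    # even split with small random jitter, keeping every exon >= min_len
    base = total // n_exons
    lens = [base] * n_exons
    lens[-1] += total - base * n_exons
    for i in range(n_exons - 1):
        shift = int(rng.integers(-(base - min_len), base - min_len + 1))
        if lens[i] + shift >= min_len and lens[i + 1] - shift >= min_len:
            lens[i] += shift
            lens[i + 1] -= shift
    return lens


def make_genome_and_annotation(spec: FixtureSpec, out_dir) -> tuple:
    """Write genome.fa and annotation.gtf; returns their paths.

    Every gene gets one designed principal transcript; the first gene of
    each biotype additionally gets lower-priority isoforms so that
    principal-transcript selection is exercised on real input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    genome_parts = []
    gtf_lines = []
    cursor = 0

    def emit(feature, start, end, strand, attrs):
        gtf_lines.append(
            f"{chrom}\tribosnitch_fixtures\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    first_of_biotype = set()
    for gi, (gene_name, biotype) in enumerate(spec.gene_table()):
        gene_id = f"G{gi + 1:03d}"
        strand = "-" if rng.random() < spec.strand_minus_fraction else "+"
        L = int(rng.integers(*spec.transcript_length_range))
        n_hp = spec.hairpins_for(gene_name)
        mature = _transcript_sequence(rng, L, n_hairpins=n_hp)
        L = len(mature)
        n_exons = int(rng.integers(2, 4))
        exon_lens = _split_exon_lengths(rng, L, n_exons)
        n_exons = len(exon_lens)
        intron_lens = [int(rng.integers(*spec.intron_length_range))
                       for _ in range(n_exons - 1)]

        spacer = _random_dna(rng, 100)
        genome_parts.append(spacer)
        cursor += len(spacer)

        # mature slices in 5'->3' order
        slices, off = [], 0
        for el in exon_lens:
            slices.append(mature[off:off + el])
            off += el
        # genomic order: ascending coordinates; on '-' the last mature exon
        # comes first and every exon is reverse-complemented
        ordered = slices if strand == "+" else [reverse_complement(s) for s in slices[::-1]]
        exon_ivals = []
        for idx, exon_seq in enumerate(ordered):
            start = cursor
            genome_parts.append(exon_seq)
            cursor += len(exon_seq)
            exon_ivals.append((start, cursor))
            if idx < len(ordered) - 1:
                intron = _random_dna(rng, intron_lens[idx])
                genome_parts.append(intron)
                cursor += len(intron)

        tid = f"{gene_id}.T1"
        gene_start, gene_end = exon_ivals[0][0], exon_ivals[-1][1]
        gattrs = (f'gene_id "{gene_id}"; gene_name "{gene_name}"; '
                  f'gene_type "{biotype}";')
        emit("gene", gene_start, gene_end, strand, gattrs)
        tattrs = (f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                  f'gene_name "{gene_name}"; gene_type "{biotype}"; level 1; '
                  f'tag "appris_principal_1"; tag "CCDS"; '
                  f'transcript_support_level "1";')
        emit("transcript", gene_start, gene_end, strand, tattrs)
        for s, e in exon_ivals:
            emit("exon", s, e, strand,
                 f'gene_id "{gene_id}"; transcript_id "{tid}";')

        if biotype == "protein_coding":
            cds_lo, cds_hi = int(0.3 * L), int(0.75 * L)
            t = Transcript(tid, gene_id, gene_name, biotype, chrom, strand,
                           exon_ivals)
            gpos = sorted(t.mature_to_genomic(k) for k in range(cds_lo, cds_hi))
            runs, run_start = [], gpos[0]
            for prev, cur in zip(gpos, gpos[1:]):
                if cur != prev + 1:
                    runs.append((run_start, prev + 1))
                    run_start = cur
            runs.append((run_start, gpos[-1] + 1))
            for s, e in runs:
                emit("CDS", s, e, strand,
                     f'gene_id "{gene_id}"; transcript_id "{tid}";')

        # extra isoforms with strictly lower priority on the first gene of
        # each biotype: exercises APPRIS > CCDS > level > length selection
        if biotype not in first_of_biotype:
            first_of_biotype.add(biotype)
            if len(exon_ivals) >= 2:
                tid2 = f"{gene_id}.T2"
                ivals2 = exon_ivals[:-1]
                a2 = (f'gene_id "{gene_id}"; transcript_id "{tid2}"; '
                      f'gene_name "{gene_name}"; gene_type "{biotype}"; level 2; '
                      f'tag "appris_principal_2";')
                emit("transcript", ivals2[0][0], ivals2[-1][1], strand, a2)
                for s, e in ivals2:
                    emit("exon", s, e, strand,
                         f'gene_id "{gene_id}"; transcript_id "{tid2}";')
                tid3 = f"{gene_id}.T3"
                ivals3 = exon_ivals[:1]
                a3 = (f'gene_id "{gene_id}"; transcript_id "{tid3}"; '
                      f'gene_name "{gene_name}"; gene_type "{biotype}";')
                emit("transcript", ivals3[0][0], ivals3[-1][1], strand, a3)
                for s, e in ivals3:
                    emit("exon", s, e, strand,
                         f'gene_id "{gene_id}"; transcript_id "{tid3}";')

    genome_parts.append(_random_dna(rng, 100))
    genome = "".join(genome_parts)
    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i:i + 60] + "\n")
    gtf_path = out_dir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    return fasta_path, gtf_path


def make_blacklist(out_path, intervals=(("chr1", 10, 40), ("chr1", 60, 80))):
    with open(out_path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return Path(out_path)


# ---------------------------------------------------------------------------
# hairpin benchmark


def make_hairpin_benchmark(
    n_pairs: int = 500,
    stem_len: int = 8,
    loop_len: int = 4,
    seed: int = 0,
    flank: int = 50,
) -> list:
    """Labelled SNV-in-context pairs from designed hairpins.

    Positives mutate an interior stem base to A, breaking a canonical
    pair in the middle of the helix (where the disruption is largest);
    negatives mutate an unpaired loop base.  Both are embedded with the
    SNV centered in a ``2*flank + 1`` nt context with weak-pairing
    flanks.
    """
    if stem_len < 4 or loop_len < 3:
        raise FixtureError("need stem_len >= 4 and loop_len >= 3")
    rng = np.random.default_rng(seed)
    total = 2 * flank + 1
    interior_lo = 2 if stem_len >= 6 else 1
    pairs = []
    for i in range(n_pairs):
        stem = "".join(rng.choice(["G", "C"], size=stem_len))
        hairpin = stem + "A" * loop_len + reverse_complement(stem)
        positive = i % 2 == 0
        if positive:
            site_in_hp = int(rng.integers(interior_lo, stem_len - interior_lo))
            ref = hairpin[site_in_hp]
            alt = "A"
            label = LABEL_POS
        else:
            site_in_hp = stem_len + int(rng.integers(0, loop_len))
            ref = "A"
            alt = "C"
            label = LABEL_NEG
        left = flank - site_in_hp
        right = total - left - len(hairpin)
        if left < 0 or right < 0:
            raise FixtureError("hairpin does not fit in the context")
        seq = (_flank_seq(rng, left) + hairpin + _flank_seq(rng, right))
        pairs.append(BenchmarkPair(f"pair{i:04d}", seq, flank, ref, alt, label))
    return pairs


def _flank_seq(rng, n):
    """Flanks from {A, C} only: cannot pair with each other."""
    return "".join(rng.choice(["A", "C"], size=n, p=[0.9, 0.1]))


# ---------------------------------------------------------------------------
# mutation cohorts


def _to_genomic_record(t: Transcript, k: int, ref_t: str, alt_t: str):
    g = t.mature_to_genomic(k)
    if t.strand == "-":
        return t.chrom, g + 1, complement(ref_t), complement(alt_t)
    return t.chrom, g + 1, ref_t, alt_t


def _score_candidates(seq, candidates, fold_config, w):
    ref_profile = pairedness_profile(seq, fold_config)
    scores = []
    for (k, ref, alt, _) in candidates:
        alt_profile = pairedness_profile(mutate_sequence(seq, k, alt), fold_config)
        s = score_profiles(ref_profile.bpp, alt_profile.bpp, k, w)
        scores.append((s.mean_diff, s.euc_diff))
    return np.array(scores)


def _select_planted(candidates, scores, n: int, effect: str) -> list:
    rm = rankdata(scores[:, 0])
    re_ = rankdata(scores[:, 1])
    if effect == "enriched":
        combined = np.minimum(rm, re_)  # high only if high in both
        order = np.argsort(-combined, kind="stable")
    else:
        combined = np.maximum(rm, re_)  # low only if low in both
        order = np.argsort(combined, kind="stable")
    return [candidates[i] for i in order[:n]]


def make_mutation_cohort(genome_path, gtf_path, spec: FixtureSpec, out_dir) -> tuple:
    """Write somatic.tsv and germline.tsv cohorts; returns their paths.

    Somatic: intronic mutations drawn from ``spec.profile_96`` (the
    neutral-profile recovery substrate) plus exonic mutations per
    noncoding element - neutral draws except planted elements, which are
    oversampled and rank-selected on the internal scorer.  Germline: the
    same elements, all neutral, disjoint sample ids.
    """
    import pyfaidx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    genome = pyfaidx.Fasta(str(genome_path))
    genes = load_annotation(gtf_path)
    principals = {
        gid: select_principal_transcript(ts) for gid, ts in sorted(genes.items())
    }
    planted_by_gene = {p.gene_name: p for p in spec.planted_elements}

    profile = MutationProfile96(spec.profile_96, "frequency", "generator")
    somatic_rows, germline_rows = [], []
    n_samples = 50

    # --- intronic somatic mutations (feed the neutral profile) -----------
    intron_sites: dict = {}
    for gid, t in principals.items():
        for (gs, ge) in t.introns():
            seq = str(genome[t.chrom][gs:ge]).upper()
            if t.strand == "-":
                seq = reverse_complement(seq)
            for p in range(1, len(seq) - 1):
                c32 = classify_position(seq, p)
                if c32 is None:
                    continue
                gpos = gs + p if t.strand == "+" else ge - 1 - p
                intron_sites.setdefault(c32, []).append(
                    (t.chrom, gpos, seq[p], t.strand)
                )
    avail = np.array([
        spec.profile_96[c] if intron_sites.get(context_class_of(c)) else 0.0
        for c in range(N_SUBSTITUTION_CLASSES)
    ])
    if avail.sum() == 0:
        raise FixtureError("no intronic sites available for the profile")
    avail = avail / avail.sum()
    from .neutral import _alt_allele_at  # reuse the collapse logic

    classes = rng.choice(N_SUBSTITUTION_CLASSES, size=spec.n_intronic_mutations,
                         p=avail)
    for mi, c96 in enumerate(classes):
        sites = intron_sites[context_class_of(int(c96))]
        chrom, gpos, base_t, strand = sites[int(rng.integers(len(sites)))]
        alt_t = _alt_allele_at(base_t, 0, int(c96))
        ref_plus = base_t if strand == "+" else complement(base_t)
        alt_plus = alt_t if strand == "+" else complement(alt_t)
        somatic_rows.append(
            (chrom, gpos + 1, ref_plus, alt_plus, f"S{mi % n_samples:03d}")
        )

    # --- exonic element mutations ----------------------------------------
    sample_counter = 0
    for gid, t in sorted(principals.items()):
        seq = extract_mature_sequence(t, genome)
        L = len(seq)
        for element_id, element_class, positions in noncoding_elements(t, L):
            # draw only positions with a full scoring window, mirroring the
            # restriction applied by the enrichment analysis
            w = spec.diff_window
            positions = [p for p in positions if w <= p <= L - 1 - w] or positions
            comp = transcript_composition(seq, positions)
            dist = recalibrate(profile, comp)
            planted = planted_by_gene.get(t.gene_name)
            n_mut = planted.n_mutations if planted else spec.mutations_per_element
            if planted is None:
                chosen = sample_mutations(seq, dist, n_mut, rng, positions)
            else:
                # oversampling scales with the fold target: locating the
                # rare high-impact sites needs a deep candidate pool
                if planted.effect == "enriched":
                    oversample = max(4, math.ceil(1.6 * planted.fold_effect))
                else:
                    oversample = max(4, math.ceil(0.4 / planted.fold_effect))
                candidates = sample_mutations(seq, dist, n_mut * oversample, rng,
                                              positions)
                scores = _score_candidates(seq, candidates, spec.fold_config,
                                           spec.diff_window)
                chosen = _select_planted(candidates, scores, n_mut, planted.effect)
            for (k, ref_t, alt_t, _) in chosen:
                chrom, pos, ref, alt = _to_genomic_record(t, k, ref_t, alt_t)
                somatic_rows.append(
                    (chrom, pos, ref, alt, f"S{sample_counter % n_samples:03d}")
                )
                sample_counter += 1
            # germline: neutral draws, no planting
            gl = sample_mutations(seq, dist, spec.mutations_per_element, rng,
                                  positions)
            for (k, ref_t, alt_t, _) in gl:
                chrom, pos, ref, alt = _to_genomic_record(t, k, ref_t, alt_t)
                germline_rows.append(
                    (chrom, pos, ref, alt, f"N{sample_counter % n_samples:03d}")
                )
                sample_counter += 1

    somatic_path = out_dir / "somatic.tsv"
    germline_path = out_dir / "germline.tsv"
    for path, rows in ((somatic_path, somatic_rows), (germline_path, germline_rows)):
        with open(path, "w") as fh:
            fh.write("# chrom\tpos\tref\talt\tsample\n")
            for chrom, pos, ref, alt, sample in rows:
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{sample}\n")
    return somatic_path, germline_path
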