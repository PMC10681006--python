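"""Synthetic fixtures: locus, diploid cohort, and error-bearing short reads.

The generator emulates the study design the genotyper targets: a single
gene locus carrying a 300-bp intron-1 insertion and a 9-bp exon-2
tandem-duplication insertion that define alleles F1/F2/F3; a germplasm
panel whose red/pink phenotypes are determined recessively by the
double-insertion homozygote; and uniform-coverage, substitution-error,
fixed-length shotgun reads.

The published diagnostic fragments around both junctions are embedded
verbatim when ``published_fragments=True`` (the default panel fixture), so
probe design reproduces the printed 60-mers byte-exactly.  Only the first
30 bp of the 300-bp intronic insert are published; the remaining 270 bp
generated here are synthetic filler, not the real sequence.

Loci are rejection-sampled so that no junction probe (either orientation)
occurs anywhere except at its own junction in any allele sequence, which
makes exact-containment support counts interpretable as junction coverage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

from .locus import (
    PINK,
    RED,
    AlleleModel,
    ConfigurationError,
    DiploidGenotype,
    Individual,
    InsertionSite,
    ReferenceLocus,
    build_allele_sequence,
    fls_allele_model,
    true_phenotype,
)
from .probes import FIXED_WINDOW, PUBLISHED_COMPAT, ProbePair, design_probe_set
from .genotyping import reverse_complement

# Published junction fragments (formatting hyphens/asterisks removed).
INTRON1_FLANK = "TCTAACTACATTTTCTCATTTTAATTTATA"          # 30 bp upstream of intron-1 site
INTRON1_INSERT_PREFIX = "GAGATATTTAGTGATATACCCATTTCTAGC"   # first 30 bp of the 300-bp insert
INTRON1_REF_DOWNSTREAM = "TTTAATAAAATTCTATTTGTTTAATTTAAT"  # 30 bp of reference after the site
EXON2_FLANK = "TTCTCGTCCCCAACGATGTCCAGGGCCTCCAG"           # 32 bp upstream of exon-2 site
EXON2_INSERT = "GGCCTCCAG"                                 # the 9-bp GLQ-duplicating insert
EXON2_REF_DOWNSTREAM = "GCCTCCAGAGATGGCCGCT"               # 19 bp of reference after the site

INTRON_SITE_ID = "intron1"
EXON_SITE_ID = "exon2"
INTRON_INSERT_LEN = 300
EXON_INSERT_LEN = 9

#: per-site upstream flank lengths matching the published probes
PUBLISHED_FLANKS = {INTRON_SITE_ID: 30, EXON_SITE_ID: 32}

#: default germplasm panel: 23 red F3F3 accessions, 169 pink accessions
#: spread over the five other genotype classes (34/34/34/34/33 split).
DEFAULT_PANEL = {
    "F3F3": 23,
    "F1F1": 34,
    "F2F2": 34,
    "F1F2": 34,
    "F1F3": 34,
    "F2F3": 33,
}

_BASES = np.array(list("ACGT"))
_ALTERNATIVES = {b: "ACGT".replace(b, "") for b in "ACGT"}
_MAX_LOCUS_ATTEMPTS = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for fixture generation."""

    seed: int
    locus_length: int = 5000
    gc_fraction: float = 0.38          # genome-wide GC of the assembly
    coverage: float = 30.0             # fold coverage per individual
    read_length: int = 150             # Illumina-style fixed read length
    error_rate: float = 0.001          # substitutions per base
    paired: bool = False
    cohort_composition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL)
    )
    phenotype_noise: float = 0.0
    window: int = 60                   # probe span the locus must support

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ConfigurationError("error_rate must be in [0, 0.1]")
        if not 0.0 <= self.phenotype_noise <= 1.0:
            raise ConfigurationError("phenotype_noise must be in [0, 1]")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        if self.read_length < self.window:
            raise ConfigurationError(
                f"read_length ({self.read_length}) must be >= probe window "
                f"({self.window})"
            )
        if any(n < 0 for n in self.cohort_composition.values()):
            raise ConfigurationError("cohort counts must be >= 0")


@dataclass(frozen=True)
class LocusFixture:
    """A generated locus with its sites, allele model, and probe params."""

    locus: ReferenceLocus
    sites: tuple[InsertionSite, ...]
    model: AlleleModel
    flank_len: Mapping[str, int]
    window: int

    def probes(self, mode: str = FIXED_WINDOW) -> dict[str, ProbePair]:
        return design_probe_set(
            self.locus, self.sites, dict(self.flank_len), self.window, mode
        )

    def allele_sequence(self, allele_name: str) -> str:
        return build_allele_sequence(
            self.locus, self.model.allele(allele_name), self.sites
        )


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode())


def random_dna(rng: np.random.Generator, n: int, gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[at, gc, gc, at]))


def _probe_counts_ok(fixture: LocusFixture) -> bool:
    """Every probe occurs exactly at its own junction and nowhere else."""
    allele_seqs = {a.name: fixture.allele_sequence(a.name) for a in fixture.model.alleles}
    for mode in (FIXED_WINDOW, PUBLISHED_COMPAT):
        for site_id, pair in fixture.probes(mode).items():
            for allele in fixture.model.alleles:
                seq = allele_seqs[allele.name]
                want_presence = 1 if allele.carries(site_id) else 0
                if seq.count(pair.presence_probe) != want_presence:
                    return False
                if seq.count(pair.absence_probe) != 1 - want_presence:
                    return False
                if seq.count(reverse_complement(pair.presence_probe)):
                    return False
                if seq.count(reverse_complement(pair.absence_probe)):
                    return False
    return True


def generate_locus(
    config: SimulationConfig,
    published_fragments: bool = False,
) -> LocusFixture:
    """Random reference with the two insertion sites and F1/F2/F3 alleles.

    With ``published_fragments=True`` the published flank / insert / downstream
    fragments are spliced in verbatim at both junctions; otherwise the
    exon insert is constructed as a tandem duplication of the 9 bases
    preceding its insertion point, and the intron insert is 300 random bp.
    """
    W = config.window
    total_insert = INTRON_INSERT_LEN + EXON_INSERT_LEN
    if config.locus_length < 2 * W + total_insert:
        raise ConfigurationError(
            f"locus_length must be >= {2 * W + total_insert} "
            f"(2 x window + total insert length), got {config.locus_length}"
        )
    rng = np.random.default_rng([config.seed, 11])
    n = config.locus_length
    pos_intron = n // 3
    pos_exon = (2 * n) // 3

    for _ in range(_MAX_LOCUS_ATTEMPTS):
        ref = list(random_dna(rng, n, config.gc_fraction))
        intron_insert = random_dna(rng, INTRON_INSERT_LEN, config.gc_fraction)
        if published_fragments:
            ref[pos_intron - 30 : pos_intron] = INTRON1_FLANK
            ref[pos_intron : pos_intron + 30] = INTRON1_REF_DOWNSTREAM
            ref[pos_exon - 32 : pos_exon] = EXON2_FLANK
            ref[pos_exon : pos_exon + 19] = EXON2_REF_DOWNSTREAM
            intron_insert = INTRON1_INSERT_PREFIX + intron_insert[30:]
            exon_insert = EXON2_INSERT
        else:
            exon_insert = "".join(ref[pos_exon - EXON_INSERT_LEN : pos_exon])
        sequence = "".join(ref)

        intron_site = InsertionSite(INTRON_SITE_ID, pos_intron, intron_insert)
        exon_site = InsertionSite(EXON_SITE_ID, pos_exon, exon_insert)
        fixture = LocusFixture(
            locus=ReferenceLocus("synthetic_fls_locus", sequence),
            sites=(intron_site, exon_site),
            model=fls_allele_model(intron_site, exon_site),
            flank_len=dict(PUBLISHED_FLANKS),
            window=W,
        )
        if _probe_counts_ok(fixture):
            return fixture
    raise ConfigurationError(
        f"could not generate a collision-free locus in {_MAX_LOCUS_ATTEMPTS} "
        "attempts; enlarge locus_length"
    )


def parse_genotype_label(label: str, model: AlleleModel) -> DiploidGenotype:
    """Split a label like 'F1F3' into a genotype of the model's alleles."""
    for name in model.allele_names:
        if label.startswith(name) and label[len(name) :] in model.allele_names:
            return DiploidGenotype.of(name, label[len(name) :])
    raise ConfigurationError(
        f"genotype label {label!r} is not a pair of alleles from "
        f"{model.allele_names}"
    )


def generate_cohort(
    config: SimulationConfig,
    model: AlleleModel,
) -> list[Individual]:
    """Individuals per the composition, phenotypes by the recessive rule.

    With ``phenotype_noise > 0`` each label is flipped independently with
    that probability (seeded), modelling scoring error.
    """
    rng = np.random.default_rng([config.seed, 22])
    cohort: list[Individual] = []
    serial = 0
    for label in sorted(config.cohort_composition):
        genotype = parse_genotype_label(label, model)
        for _ in range(config.cohort_composition[label]):
            serial += 1
            phenotype = true_phenotype(genotype, model)
            if config.phenotype_noise > 0 and rng.random() < config.phenotype_noise:
                phenotype = PINK if phenotype == RED else RED
            cohort.append(Individual(f"acc{serial:03d}", genotype, phenotype))
    return cohort


@dataclass
class ReadSet:
    """Simulated reads for one individual, with per-read truth labels."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    source_individual: str
    truth: list[str]  # "allele:start" per read (paired mode: per fragment)

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.reads]


def _apply_errors(
    seq: str, n_err: int, rng: np.random.Generator
) -> str:
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = _ALTERNATIVES[out[pos]][rng.integers(3)]
    return "".join(out)


def simulate_reads(
    individual: Individual,
    fixture: LocusFixture,
    config: SimulationConfig,
) -> ReadSet:
    """Uniform-coverage fixed-length reads from the individual's haplotypes.

    Total read count is round(coverage x mean haplotype length / L); each
    read's haplotype is a fair coin, start positions uniform, substitution
    errors i.i.d. at ``error_rate`` to a uniformly chosen different base.
    Paired mode emits round(.../2L) pairs from fixed 2L fragments (mate 2
    reverse-complemented), honoring the same total base yield.
    """
    if individual.genotype is None:
        raise ConfigurationError(f"individual {individual.id!r} has no genotype")
    L = config.read_length
    haps = [
        fixture.allele_sequence(individual.genotype.allele_a),
        fixture.allele_sequence(individual.genotype.allele_b),
    ]
    hap_names = (individual.genotype.allele_a, individual.genotype.allele_b)
    span = 2 * L if config.paired else L
    for h in haps:
        if len(h) < span:
            raise ConfigurationError(
                f"haplotype shorter than {'fragment' if config.paired else 'read'} "
                f"length ({len(h)} < {span})"
            )
    mean_len = (len(haps[0]) + len(haps[1])) / 2.0
    n_units = round(config.coverage * mean_len / span)

    rng = np.random.default_rng([config.seed, 33, _stable_hash(individual.id)])
    hap_idx = rng.integers(0, 2, size=n_units)
    reads: list[tuple[str, str, str]] = []
    truth: list[str] = []
    qual = "I" * L
    for i in range(n_units):
        h = int(hap_idx[i])
        hap = haps[h]
        start = int(rng.integers(0, len(hap) - span + 1))
        fragment = hap[start : start + span]
        truth.append(f"{hap_names[h]}:{start}")
        if config.paired:
            mates = (fragment[:L], reverse_complement(fragment[L:]))
            for mate_no, mate in enumerate(mates, start=1):
                seq = _apply_errors(mate, int(rng.binomial(L, config.error_rate)), rng)
                reads.append((f"{individual.id}:r{i:05d}/{mate_no}", seq, qual))
        else:
            seq = _apply_errors(fragment, int(rng.binomial(L, config.error_rate)), rng)
            reads.append((f"{individual.id}:r{i:05d}", seq, qual))
    return ReadSet(reads=reads, source_individual=individual.id, truth=truth)


def simulate_cohort_reads(
    cohort: Iterable[Individual],
    fixture: LocusFixture,
    config: SimulationConfig,
) -> Iterator[ReadSet]:
    for individual in cohort:
        yield simulate_reads(individual, fixture, config)
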