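"""Locus, insertion-site and allele model for presence/absence genotyping.

The model describes a single gene region — in the motivating analysis, the
peach *FLS* (flavonol synthase) locus — together with candidate insertion
sites.  An allele is defined purely by the subset of insertions it carries;
a diploid genotype is an unordered pair of alleles.  The default three-allele
lattice is

* ``F1`` — no insertion,
* ``F2`` — the 300-bp intron-1 insertion only,
* ``F3`` — both the intron-1 insertion and the 9-bp exon-2 insertion,

with the *nested* constraint that any allele carrying the exonic insertion
also carries the intronic one (no fourth allele class is modelled because
none is observed).

Coordinates are 0-based throughout; an insertion at position ``p`` sits
between reference bases ``p-1`` and ``p`` ("insert before p"), which is
well defined at both sequence ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

VALID_BASES = frozenset("ACGT")

RED = "red"
PINK = "pink"
UNKNOWN = "unknown"
PHENOTYPES = frozenset({RED, PINK, UNKNOWN})


class ConfigurationError(ValueError):
    """Inconsistent site / allele / model definitions."""


class SequenceError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


class BoundsError(ValueError):
    """A coordinate falls outside the reference locus."""


def check_dna(seq: str, what: str = "sequence") -> None:
    """Reject anything outside uppercase A/C/G/T (ambiguity codes included)."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(
            f"{what} contains non-ACGT characters {sorted(bad)!r}; "
            "ambiguity codes such as N are rejected at load"
        )


@dataclass(frozen=True)
class ReferenceLocus:
    """A single contiguous reference sequence (0-based coordinates)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"locus {self.id!r}: empty sequence")
        check_dna(self.sequence, f"locus {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InsertionSite:
    """A candidate insertion placed immediately before ``position``."""

    site_id: str
    position: int
    insert_seq: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise BoundsError(f"site {self.site_id!r}: negative position")
        if not self.insert_seq:
            raise ConfigurationError(f"site {self.site_id!r}: empty insert")
        check_dna(self.insert_seq, f"site {self.site_id!r} insert")


@dataclass(frozen=True)
class AlleleDef:
    """An allele, identified by the set of insertion sites it carries."""

    name: str
    present_sites: frozenset[str] = field(default_factory=frozenset)

    def carries(self, site_id: str) -> bool:
        return site_id in self.present_sites


@dataclass(frozen=True, order=True)
class DiploidGenotype:
    """An unordered pair of allele names; ``allele_a <= allele_b``."""

    allele_a: str
    allele_b: str

    @classmethod
    def of(cls, a: str, b: str) -> "DiploidGenotype":
        lo, hi = sorted((a, b))
        return cls(lo, hi)

    @property
    def name(self) -> str:
        return self.allele_a + self.allele_b

    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b


@dataclass
class Individual:
    """A cohort member with (possibly unknown) genotype and phenotype."""

    id: str
    genotype: DiploidGenotype | None = None
    phenotype: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(
                f"individual {self.id!r}: phenotype {self.phenotype!r} not in "
                f"{sorted(PHENOTYPES)}"
            )


@dataclass(frozen=True)
class AlleleModel:
    """The allele lattice over a set of insertion sites.

    ``causal_site`` names the insertion whose homozygous presence determines
    the recessive phenotype (the exon-2 insert in the red-flower model).
    With ``nested=True`` every allele carrying ``causal_site`` must also
    carry every other declared site (exon insert implies intron insert).
    """

    alleles: tuple[AlleleDef, ...]
    sites: tuple[InsertionSite, ...]
    causal_site: str
    nested: bool = True

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate allele names: {names}")
        site_ids = {s.site_id for s in self.sites}
        if self.causal_site not in site_ids:
            raise ConfigurationError(
                f"causal site {self.causal_site!r} not among sites {sorted(site_ids)}"
            )
        for allele in self.alleles:
            stray = allele.present_sites - site_ids
            if stray:
                raise ConfigurationError(
                    f"allele {allele.name!r} references undeclared sites {sorted(stray)}"
                )
            if self.nested and allele.carries(self.causal_site):
                missing = site_ids - allele.present_sites
                if missing:
                    raise ConfigurationError(
                        f"nested model: allele {allele.name!r} carries the causal "
                        f"site but lacks {sorted(missing)}"
                    )

    def allele(self, name: str) -> AlleleDef:
        for a in self.alleles:
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown allele {name!r}")

    def site(self, site_id: str) -> InsertionSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise ConfigurationError(f"unknown site {site_id!r}")

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)

    def genotypes(self) -> list[DiploidGenotype]:
        return enumerate_genotypes(self.alleles)

    def is_recessive_homozygote(self, genotype: DiploidGenotype) -> bool:
        """True when both alleles carry the causal insertion."""
        return all(
            self.allele(name).carries(self.causal_site)
            for name in (genotype.allele_a, genotype.allele_b)
        )


def build_allele_sequence(
    locus: ReferenceLocus,
    allele: AlleleDef,
    sites: Iterable[InsertionSite],
) -> str:
    """Materialize an allele's sequence by splicing its insertions.

    Insertions are applied in descending coordinate order so every stored
    position remains a reference coordinate (earlier positions unshifted).
    The result length is ``len(locus)`` plus the summed insert lengths.
    """
    by_id = {}
    for s in sites:
        if s.site_id in by_id:
            raise ConfigurationError(f"duplicate site id {s.site_id!r}")
        by_id[s.site_id] = s
    chosen = []
    for site_id in allele.present_sites:
        if site_id not in by_id:
            raise ConfigurationError(
                f"allele {allele.name!r} references unknown site {site_id!r}"
            )
        chosen.append(by_id[site_id])
    seq = locus.sequence
    for site in sorted(chosen, key=lambda s: s.position, reverse=True):
        if site.position > len(locus):
            raise BoundsError(
                f"site {site.site_id!r} position {site.position} exceeds locus "
                f"length {len(locus)}"
            )
        seq = seq[: site.position] + site.insert_seq + seq[site.position :]
    return seq


def enumerate_genotypes(alleles: Sequence[AlleleDef]) -> list[DiploidGenotype]:
    """All unordered allele pairs with replacement, lexicographic order."""
    names = [a.name for a in alleles]
    if not names:
        raise ConfigurationError("need at least one allele")
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate allele names: {names}")
    return [
        DiploidGenotype.of(a, b)
        for a, b in combinations_with_replacement(sorted(names), 2)
    ]


def fls_allele_model(
    intron_site: InsertionSite,
    exon_site: InsertionSite,
    nested: bool = True,
) -> AlleleModel:
    """The default F1/F2/F3 lattice over an intronic and an exonic insertion."""
    f1 = AlleleDef("F1", frozenset())
    f2 = AlleleDef("F2", frozenset({intron_site.site_id}))
    f3 = AlleleDef("F3", frozenset({intron_site.site_id, exon_site.site_id}))
    return AlleleModel(
        alleles=(f1, f2, f3),
        sites=(intron_site, exon_site),
        causal_site=exon_site.site_id,
        nested=nested,
    )


def true_phenotype(genotype: DiploidGenotype, model: AlleleModel) -> str:
    """Recessive rule: red iff homozygous for the causal insertion."""
    return RED if model.is_recessive_homozygote(genotype) else PINK
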