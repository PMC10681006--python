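"""Exact-match read screening and diploid genotype inference.

A read supports a probe only if it contains the probe as an exact,
full-length, contiguous substring — any mismatch, gap or N in the span
disqualifies it ("100% identity over the full probe length").  By default
both the given orientation and its reverse complement are searched, since
shotgun reads sample both strands; ``both_strands=False`` restricts to
literal containment.

Per-site presence/absence support counts are reduced to one of four states
(REF / HET / HOM_INS / NO_CALL) by a minimum-support threshold ``m``, and
the per-site states are jointly mapped to a diploid genotype by enumerating
the allele model's genotype space: a state combination reachable by exactly
one genotype yields that call, an unreachable combination is INCONSISTENT
(it would require a haplotype outside the model, e.g. an exon insertion
without the intron insertion under the nested lattice), and any NO_CALL
input propagates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .locus import (
    PINK,
    RED,
    UNKNOWN,
    AlleleModel,
    ConfigurationError,
    DiploidGenotype,
)
from .probes import ProbePair

logger = logging.getLogger(__name__)

REF = "REF"
HET = "HET"
HOM_INS = "HOM_INS"
NO_CALL = "NO_CALL"
INCONSISTENT = "INCONSISTENT"

_COMPLEMENT = str.maketrans("ACGTN", "TACGN")

#: minor-support fraction below which a HET call logs a warning
MINOR_FRACTION_WARN = 0.1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def screen_reads(
    reads: Iterable[str],
    probe: str,
    both_strands: bool = True,
) -> int:
    """Count reads containing ``probe`` exactly (either strand by default).

    Raises ``ConfigurationError`` if a read is shorter than the probe —
    a probe that cannot fit in a read must not be silently scored 0.
    """
    rc = reverse_complement(probe) if both_strands else None
    count = 0
    plen = len(probe)
    for read in reads:
        if len(read) < plen:
            raise ConfigurationError(
                f"probe ({plen} bp) longer than read ({len(read)} bp); "
                "screening requires probe length <= read length"
            )
        if probe in read or (rc is not None and rc in read):
            count += 1
    return count


@dataclass(frozen=True)
class SiteCall:
    site_id: str
    presence_support: int
    absence_support: int
    state: str
    min_support: int


def call_state(presence_support: int, absence_support: int, min_support: int) -> str:
    """Reduce support counts to a site state under threshold ``m``."""
    if min_support < 1:
        raise ConfigurationError(f"min_support must be >= 1, got {min_support}")
    if presence_support < 0 or absence_support < 0:
        raise ConfigurationError("support counts must be non-negative")
    p_ok = presence_support >= min_support
    a_ok = absence_support >= min_support
    if p_ok and a_ok:
        return HET
    if p_ok:
        return HOM_INS
    if a_ok:
        return REF
    return NO_CALL


def call_site(
    site_id: str,
    presence_support: int,
    absence_support: int,
    min_support: int = 1,
) -> SiteCall:
    state = call_state(presence_support, absence_support, min_support)
    if state == HET:
        total = presence_support + absence_support
        minor = min(presence_support, absence_support) / total
        if minor < MINOR_FRACTION_WARN:
            logger.warning(
                "site %s: HET with skewed support %d/%d (minor fraction %.3f)",
                site_id, presence_support, absence_support, minor,
            )
    return SiteCall(site_id, presence_support, absence_support, state, min_support)


def _genotype_state_table(model: AlleleModel) -> dict[tuple[str, ...], DiploidGenotype]:
    """Map per-site state vectors (in model.sites order) to genotypes."""
    state_of = {0: REF, 1: HET, 2: HOM_INS}
    table: dict[tuple[str, ...], DiploidGenotype] = {}
    for gt in model.genotypes():
        pair = (model.allele(gt.allele_a), model.allele(gt.allele_b))
        key = tuple(
            state_of[sum(a.carries(s.site_id) for a in pair)] for s in model.sites
        )
        if key in table:
            raise ConfigurationError(
                f"allele model is not identifiable from site states: "
                f"{table[key].name} and {gt.name} share {key}"
            )
        table[key] = gt
    return table


@dataclass
class GenotypeCall:
    individual_id: str
    genotype: DiploidGenotype | None
    label: str  # genotype name, or INCONSISTENT / NO_CALL
    site_calls: list[SiteCall] = field(default_factory=list)
    predicted_phenotype: str = UNKNOWN


def infer_genotype(
    site_calls: Sequence[SiteCall],
    model: AlleleModel,
    individual_id: str = "",
) -> GenotypeCall:
    """Resolve per-site calls into a diploid genotype under the allele model."""
    order = [s.site_id for s in model.sites]
    by_id = {c.site_id: c for c in site_calls}
    missing = [s for s in order if s not in by_id]
    if missing:
        raise ConfigurationError(f"missing site calls for {missing}")
    ordered = [by_id[s] for s in order]

    if any(c.state == NO_CALL for c in ordered):
        label, genotype = NO_CALL, None
    else:
        key = tuple(c.state for c in ordered)
        genotype = _genotype_state_table(model).get(key)
        label = genotype.name if genotype is not None else INCONSISTENT

    call = GenotypeCall(individual_id, genotype, label, list(ordered))
    call.predicted_phenotype = predict_phenotype(call, model)
    return call


def predict_phenotype(call: GenotypeCall | DiploidGenotype, model: AlleleModel) -> str:
    """Recessive rule: red iff homozygous for the causal insertion allele."""
    genotype = call.genotype if isinstance(call, GenotypeCall) else call
    if genotype is None:
        return UNKNOWN
    return RED if model.is_recessive_homozygote(genotype) else PINK


def genotype_reads(
    reads: Iterable[str],
    probes: Mapping[str, ProbePair],
    model: AlleleModel,
    min_support: int = 1,
    individual_id: str = "",
    both_strands: bool = True,
) -> GenotypeCall:
    """Screen one individual's reads against every probe pair and call."""
    reads = list(reads)
    site_calls = []
    for site in model.sites:
        pair = probes[site.site_id]
        pres = screen_reads(reads, pair.presence_probe, both_strands)
        absn = screen_reads(reads, pair.absence_probe, both_strands)
        site_calls.append(call_site(site.site_id, pres, absn, min_support))
    return infer_genotype(site_calls, model, individual_id)
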