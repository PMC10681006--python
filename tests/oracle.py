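"""Brute-force genotyping oracle, independent of the probe machinery.

Instead of composing probes from the reference and insert, the oracle
slices junction windows directly out of each *allele sequence* (shifting
site coordinates by upstream insert lengths), checks which window strings
are contained in the read set (either orientation), and finds the genotype
whose two alleles' windows exactly explain the supported set.  Used to
cross-check the junction-probe genotyper on error-free reads.
"""

from __future__ import annotations

from peachfls import build_allele_sequence, reverse_complement


def allele_junction_windows(fixture, allele_name: str) -> frozenset[str]:
    """One window per site, sliced from the allele's own sequence."""
    model = fixture.model
    allele = model.allele(allele_name)
    seq = build_allele_sequence(fixture.locus, allele, fixture.sites)
    windows = set()
    for site in fixture.sites:
        shift = sum(
            len(model.site(other).insert_seq)
            for other in allele.present_sites
            if model.site(other).position < site.position
        )
        jpos = site.position + shift
        f = fixture.flank_len[site.site_id]
        windows.add(seq[jpos - f : jpos - f + fixture.window])
    return frozenset(windows)


def oracle_genotype(read_seqs: list[str], fixture) -> str | None:
    """Label of the unique genotype explaining the supported windows, else None."""
    model = fixture.model
    per_allele = {a.name: allele_junction_windows(fixture, a.name) for a in model.alleles}
    universe = frozenset().union(*per_allele.values())
    supported = frozenset(
        w for w in universe
        if any(w in r or reverse_complement(w) in r for r in read_seqs)
    )
    matches = [
        gt for gt in model.genotypes()
        if per_allele[gt.allele_a] | per_allele[gt.allele_b] == supported
    ]
    return matches[0].name if len(matches) == 1 else None
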