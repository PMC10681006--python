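"""End-to-end pipeline: probes -> reads -> genotypes -> association -> insert report.

Two entry points:

* ``run_synthetic_pipeline`` generates everything from a seed (locus fixture,
  cohort, reads) and runs the full analysis — the reproducible study-in-a-box.
* ``genotype_files`` genotypes existing FASTQ/FASTA read files against a
  supplied locus + site config, for externally produced reads.

All artifacts are deterministic functions of the configuration: output files
carry the seed and a parameter fingerprint in their headers and contain no
timestamps, so reruns with equal fingerprints are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from . import io as pio
from .association import DEFAULT_THRESHOLD, associate, build_table, mendelian_report
from .characterize import characterize_insert
from .genotyping import GenotypeCall, genotype_reads
from .locus import ConfigurationError
from .probes import FIXED_WINDOW
from .simulate import (
    EXON_SITE_ID,
    LocusFixture,
    SimulationConfig,
    generate_cohort,
    generate_locus,
    simulate_reads,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: Path
    simulation: SimulationConfig
    min_support: int = 2
    threshold: float = DEFAULT_THRESHOLD
    probe_mode: str = FIXED_WINDOW
    published_fragments: bool = True
    write_reads: bool = False  # FASTQ per individual is bulky; off by default
    exon_frame: int = 0

    def fingerprint(self) -> str:
        doc = dataclasses.asdict(self)
        doc["out_dir"] = None  # output location must not change the fingerprint
        doc["simulation"]["cohort_composition"] = dict(
            sorted(self.simulation.cohort_composition.items())
        )
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> str:
    return f"peachfls seed={config.simulation.seed} fingerprint={config.fingerprint()}"


def run_synthetic_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Generate, genotype, associate and characterize; return artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    artifacts: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # named-stage abort
                raise PipelineError(name, exc) from exc
        return wrap

    def stage_fixture():
        fixture = generate_locus(config.simulation, published_fragments=config.published_fragments)
        pio.write_fasta(out / "locus.fasta", [(fixture.locus.id, fixture.locus.sequence)])
        pio.dump_sites_alleles(out / "sites_alleles.yaml", fixture.model)
        probes = fixture.probes(config.probe_mode)
        pio.write_probe_fasta(out / "probes.fasta", probes)
        pio.write_probe_manifest(out / "probes.tsv", probes)
        artifacts.update(
            locus=out / "locus.fasta", sites=out / "sites_alleles.yaml",
            probes=out / "probes.fasta", probe_manifest=out / "probes.tsv",
        )
        return fixture, probes

    fixture, probes = _stage("design-probes")(stage_fixture)

    def stage_cohort():
        cohort = generate_cohort(config.simulation, fixture.model)
        if not cohort:
            raise ConfigurationError("empty cohort composition")
        pio.write_tsv(out / "cohort_truth.tsv", pio.cohort_frame(cohort), prov)
        artifacts["cohort_truth"] = out / "cohort_truth.tsv"
        return cohort

    cohort = _stage("simulate")(stage_cohort)

    def stage_genotype():
        calls: list[GenotypeCall] = []
        reads_dir = out / "reads"
        if config.write_reads:
            reads_dir.mkdir(exist_ok=True)
        for individual in cohort:
            readset = simulate_reads(individual, fixture, config.simulation)
            if config.write_reads:
                pio.write_fastq(reads_dir / f"{individual.id}.fastq.gz", readset)
            calls.append(
                genotype_reads(
                    readset.sequences(), probes, fixture.model,
                    min_support=config.min_support, individual_id=individual.id,
                )
            )
        pio.write_tsv(out / "genotypes.tsv", pio.genotype_frame(calls), prov)
        artifacts["genotypes"] = out / "genotypes.tsv"
        return calls

    calls = _stage("genotype")(stage_genotype)

    def stage_associate():
        phenotype_of = {ind.id: ind.phenotype for ind in cohort}
        records = [(c.label, phenotype_of[c.individual_id]) for c in calls]
        table = build_table(records)
        result = associate(table, config.threshold)
        frame = pd.DataFrame(
            [{
                "variant_id": EXON_SITE_ID, "a": table.a, "b": table.b,
                "c": table.c, "d": table.d, "p_two_sided": result.p_two_sided,
                "odds_ratio": result.odds_ratio,
                "or_continuity_corrected": result.or_continuity_corrected,
                "penetrance": result.penetrance, "specificity": result.specificity,
                "cosegregates": result.cosegregates,
                "significant": result.significant,
            }]
        )
        pio.write_tsv(out / "association.tsv", frame, prov)
        mendel = mendelian_report(
            (c.individual_id, c.label, phenotype_of[c.individual_id]) for c in calls
        )
        with open(out / "mendelian_report.txt", "w") as fh:
            fh.write(f"# {prov}\n")
            fh.write("Factor mapping: F1,F2 -> R ; F3 -> r\n")
            for factor in sorted(mendel.class_counts):
                for phenotype, n in sorted(mendel.class_counts[factor].items()):
                    fh.write(f"{factor}\t{phenotype}\t{n}\n")
            fh.write(f"consistent_with_recessive_model: {mendel.consistent}\n")
            if mendel.violations:
                fh.write("violations: " + ",".join(mendel.violations) + "\n")
        artifacts["association"] = out / "association.tsv"
        artifacts["mendelian_report"] = out / "mendelian_report.txt"
        return result

    result = _stage("associate")(stage_associate)

    def stage_characterize():
        site = fixture.model.site(EXON_SITE_ID)
        char = characterize_insert(fixture.locus, site, frame=config.exon_frame)
        doc = dataclasses.asdict(char)
        doc["provenance"] = prov
        with open(out / "characterization.json", "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts["characterization"] = out / "characterization.json"

    _stage("characterize")(stage_characterize)

    manifest = {
        "package": "peachfls",
        "version": __version__,
        "seed": config.simulation.seed,
        "fingerprint": config.fingerprint(),
        "parameters": {
            "min_support": config.min_support,
            "threshold": config.threshold,
            "probe_mode": config.probe_mode,
            "published_fragments": config.published_fragments,
            "simulation": {
                **dataclasses.asdict(config.simulation),
                "cohort_composition": dict(sorted(config.simulation.cohort_composition.items())),
            },
        },
        "cosegregation_p": result.p_two_sided,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = out / "manifest.json"
    return artifacts


def genotype_files(
    locus_fasta: Path,
    sites_yaml: Path,
    reads: Mapping[str, Path],
    flank_len: Mapping[str, int] | int,
    window: int = 60,
    mode: str = FIXED_WINDOW,
    min_support: int = 1,
    both_strands: bool = True,
) -> list[GenotypeCall]:
    """Genotype per-individual FASTQ/FASTA files against a locus + site config."""
    from .probes import design_probe_set

    locus = pio.read_locus(locus_fasta)
    sites, model = pio.load_sites_alleles(sites_yaml)
    probes = design_probe_set(locus, sites, flank_len, window, mode)
    calls = []
    for individual_id, path in sorted(reads.items()):
        path = Path(path)
        if path.suffix in (".fasta", ".fa") or path.name.endswith((".fasta.gz", ".fa.gz")):
            seqs = [seq for _, seq in pio.read_fasta(path)]
        else:
            seqs = pio.read_fastq(path, individual_id).sequences()
        calls.append(
            genotype_reads(seqs, probes, model, min_support, individual_id,
                           both_strands=both_strands)
        )
    return calls
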