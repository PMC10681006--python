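"""File formats: FASTA, FASTQ(.gz), TSV tables, YAML site/allele configs.

FASTA parsing is delegated to Biopython's ``SeqIO``; writing emits 60-column
wrapped records directly so that round-tripping a wrapped input is
byte-stable.  The single tabular dialect is TSV: tab separated, header row,
UTF-8, no quoting, '.' decimal.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .locus import (
    AlleleDef,
    AlleleModel,
    ConfigurationError,
    InsertionSite,
    ReferenceLocus,
    check_dna,
)
from .genotyping import GenotypeCall
from .probes import ProbePair
from .simulate import ReadSet

FASTA_WRAP = 60


class ParseError(ValueError):
    """Malformed input file."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records as (id, sequence); empty or headerless files are errors."""
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header '>', got {line[:20]!r}"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_locus(path: str | Path) -> ReferenceLocus:
    records = read_fasta(path)
    if len(records) != 1:
        raise ParseError(f"{path}: expected a single-record locus FASTA, got {len(records)}")
    rec_id, seq = records[0]
    return ReferenceLocus(rec_id, seq)


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str | Path, source_individual: str = "") -> ReadSet:
    """Four-line Sanger/Phred+33 records; gzip transparent."""
    path = Path(path)
    reads: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not any(ln.strip() for ln in lines):
        raise ParseError(f"{path}: empty FASTQ file")
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ record (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}:{i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{i + 3}: expected '+' separator, got {plus[:20]!r}")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}:{i + 2}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        reads.append((head[1:].split()[0], seq.upper(), qual))
    source = source_individual or path.name.split(".")[0]
    return ReadSet(reads=reads, source_individual=source, truth=[])


def write_fastq(path: str | Path, readset: ReadSet) -> None:
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in readset.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------- probes

def write_probe_fasta(path: str | Path, probes: Mapping[str, ProbePair]) -> None:
    records = []
    for site_id in sorted(probes):
        pair = probes[site_id]
        records.append((f"{site_id}.presence", pair.presence_probe))
        records.append((f"{site_id}.absence", pair.absence_probe))
    write_fasta(path, records)


def write_probe_manifest(path: str | Path, probes: Mapping[str, ProbePair]) -> None:
    rows = [
        {
            "site_id": site_id,
            "mode": pair.mode,
            "flank_len": pair.flank_len,
            "window": pair.window,
            "presence_len": len(pair.presence_probe),
            "absence_len": len(pair.absence_probe),
        }
        for site_id, pair in sorted(probes.items())
    ]
    write_tsv(path, pd.DataFrame(rows))


# ---------------------------------------------------------------- tables

def write_tsv(path: str | Path, frame: pd.DataFrame, header_comment: str | None = None) -> None:
    """TSV with an optional leading '# ...' provenance line (seed, fingerprint)."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def cohort_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [ind.id for ind in cohort],
            "genotype": [ind.genotype.name if ind.genotype else "unknown" for ind in cohort],
            "phenotype": [ind.phenotype for ind in cohort],
        }
    )


def genotype_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {"individual_id": call.individual_id, "genotype": call.label,
               "predicted_phenotype": call.predicted_phenotype}
        for sc in call.site_calls:
            row[f"{sc.site_id}_state"] = sc.state
            row[f"{sc.site_id}_presence_support"] = sc.presence_support
            row[f"{sc.site_id}_absence_support"] = sc.absence_support
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- config

def load_sites_alleles(path: str | Path) -> tuple[list[InsertionSite], AlleleModel]:
    """YAML schema::

        sites:
          - {site_id: intron1, position: 1666, insert_seq: GAGA...}
        alleles:
          F1: []
          F2: [intron1]
          F3: [intron1, exon2]
        model:
          causal_site: exon2
          nested: true
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        sites = [
            InsertionSite(s["site_id"], int(s["position"]), str(s["insert_seq"]).upper())
            for s in doc["sites"]
        ]
        alleles = tuple(
            AlleleDef(name, frozenset(site_list or []))
            for name, site_list in doc["alleles"].items()
        )
        model_cfg = doc["model"]
        model = AlleleModel(
            alleles=alleles,
            sites=tuple(sites),
            causal_site=model_cfg["causal_site"],
            nested=bool(model_cfg.get("nested", True)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"{path}: malformed sites/alleles config: {exc}") from exc
    return sites, model


def dump_sites_alleles(path: str | Path, model: AlleleModel) -> None:
    doc = {
        "sites": [
            {"site_id": s.site_id, "position": s.position, "insert_seq": s.insert_seq}
            for s in model.sites
        ],
        "alleles": {a.name: sorted(a.present_sites) for a in model.alleles},
        "model": {"causal_site": model.causal_site, "nested": model.nested},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
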