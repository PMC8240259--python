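"""On-disk and in-memory representation of a community data bundle.

A bundle collects everything the analysis consumes for one study:
contig sequences, the per-gene annotation table, detector categories,
per-genus CRISPR spacer libraries, per-sample feature count tables,
induction-assay triplets, sample metadata and (for synthetic
communities) the ground-truth manifest.  The on-disk layout is plain
text:

    contigs.fasta
    annotations.tsv      gene_id contig_id start end strand vpf_hit pfam_hit ko_hit eggnog_cat
    virsorter.tsv        contig_id category
    samples.tsv          sample_id stress
    spacers/<genus>.fasta
    counts_<sample>.tsv  feature_id read_count feature_length_nt
    induction.tsv        sample_id vi vck b
    manifest.json        (synthetic bundles only)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .hosts import Spacer
from .lysogeny import InductionMeasurement

ANNOTATION_COLUMNS = [
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "vpf_hit",
    "pfam_hit",
    "ko_hit",
    "eggnog_cat",
]


@dataclass
class GroundTruthManifest:
    """Known truth for a synthetic community.

    ``contigs`` maps contig id to its planted lifestyle, host genera and
    MRG genes; ``samples`` maps sample id to realised per-sample
    quantities (lysogeny and polyvalence fractions under the same
    weighting the pipeline uses, MRG-on-lysogen fractions, integrase
    percentage and the true induced-phage-per-cell value).
    """

    config: dict[str, Any] = field(default_factory=dict)
    contigs: dict[str, dict[str, Any]] = field(default_factory=dict)
    samples: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"config": self.config, "contigs": self.contigs, "samples": self.samples}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "GroundTruthManifest":
        return cls(
            config=data.get("config", {}),
            contigs=data.get("contigs", {}),
            samples=data.get("samples", {}),
        )


@dataclass
class Bundle:
    """All inputs for one end-to-end analysis run."""

    contigs: dict[str, str]
    annotations: pd.DataFrame
    virsorter: pd.DataFrame
    spacers: dict[str, list[Spacer]]
    counts: dict[str, pd.DataFrame]
    induction: pd.DataFrame
    samples: pd.DataFrame
    manifest: GroundTruthManifest | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def contig_lengths(self) -> pd.Series:
        return pd.Series({cid: len(seq) for cid, seq in self.contigs.items()})

    def all_spacers(self) -> list[Spacer]:
        return [sp for genus in sorted(self.spacers) for sp in self.spacers[genus]]

    def induction_for(self, sample_id: str) -> InductionMeasurement | None:
        rows = self.induction[self.induction["sample_id"] == sample_id]
        if rows.empty:
            return None
        row = rows.iloc[0]
        return InductionMeasurement(
            sample_id=sample_id, vi=float(row["vi"]), vck=float(row["vck"]), b=float(row["b"])
        )

    def write(self, path: str | Path) -> Path:
        """Write the bundle as plain-text files; byte-stable for a fixed seed."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(seq), id=cid, description="") for cid, seq in self.contigs.items()
        ]
        SeqIO.write(records, path / "contigs.fasta", "fasta")
        self.annotations.to_csv(
            path / "annotations.tsv", sep="\t", index=False, na_rep=""
        )
        self.virsorter.to_csv(path / "virsorter.tsv", sep="\t", index=False)
        self.samples.to_csv(path / "samples.tsv", sep="\t", index=False)
        spacer_dir = path / "spacers"
        spacer_dir.mkdir(exist_ok=True)
        for genus in sorted(self.spacers):
            recs = [
                SeqRecord(Seq(sp.sequence), id=sp.spacer_id, description="")
                for sp in self.spacers[genus]
            ]
            SeqIO.write(recs, spacer_dir / f"{genus}.fasta", "fasta")
        for sample_id, table in self.counts.items():
            table.to_csv(path / f"counts_{sample_id}.tsv", sep="\t", index=False)
        self.induction.to_csv(path / "induction.tsv", sep="\t", index=False)
        if self.manifest is not None:
            with open(path / "manifest.json", "w") as fh:
                json.dump(self.manifest.to_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "Bundle":
        path = Path(path)
        if not (path / "contigs.fasta").exists():
            raise InputError(f"{path}: not a bundle directory (missing contigs.fasta)")
        contigs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(path / "contigs.fasta", "fasta")
        }
        annotations = pd.read_csv(
            path / "annotations.tsv", sep="\t", dtype={"gene_id": str, "contig_id": str}
        )
        virsorter = pd.read_csv(path / "virsorter.tsv", sep="\t")
        samples = pd.read_csv(path / "samples.tsv", sep="\t")
        spacers: dict[str, list[Spacer]] = {}
        spacer_dir = path / "spacers"
        if spacer_dir.exists():
            for fasta in sorted(spacer_dir.glob("*.fasta")):
                genus = fasta.stem
                spacers[genus] = [
                    Spacer(spacer_id=rec.id, genus=genus, sequence=str(rec.seq))
                    for rec in SeqIO.parse(fasta, "fasta")
                ]
        counts = {
            sid: pd.read_csv(path / f"counts_{sid}.tsv", sep="\t")
            for sid in samples["sample_id"]
            if (path / f"counts_{sid}.tsv").exists()
        }
        induction_path = path / "induction.tsv"
        induction = (
            pd.read_csv(induction_path, sep="\t")
            if induction_path.exists()
            else pd.DataFrame(columns=["sample_id", "vi", "vck", "b"])
        )
        manifest = None
        if (path / "manifest.json").exists():
            with open(path / "manifest.json") as fh:
                manifest = GroundTruthManifest.from_dict(json.load(fh))
        return cls(
            contigs=contigs,
            annotations=annotations,
            virsorter=virsorter,
            spacers=spacers,
            counts=counts,
            induction=induction,
            samples=samples,
            manifest=manifest,
        )
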