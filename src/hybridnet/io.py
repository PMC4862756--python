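"""File formats: FASTA, intensity/E-score/calls TSV, region BED."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import BindingRegion
from .simulate.arrays import ProbeSet
from .simulate.intensities import IntensitySample


def read_fasta(path) -> dict[str, str]:
    """id -> sequence mapping from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_probes(path) -> ProbeSet:
    seqs = read_fasta(path)
    return ProbeSet(ids=list(seqs), sequences=list(seqs.values()))


def write_probes(probes: ProbeSet, path) -> None:
    write_fasta(dict(zip(probes.ids, probes.sequences)), path)


def read_intensities(path) -> IntensitySample:
    """Two-column TSV (probe_id, intensity)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "intensity"])
    return IntensitySample(
        probe_ids=df["probe_id"].astype(str).tolist(),
        values=df["intensity"].to_numpy(float),
    )


def write_intensities(sample: IntensitySample, path) -> None:
    pd.DataFrame({"probe_id": sample.probe_ids, "intensity": sample.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_labels(labels: Mapping[str, str], path) -> None:
    pd.Series(labels, name="label").rename_axis("id").to_csv(path, sep="\t")


def read_calls(path) -> pd.DataFrame:
    """Genome x family member-count table (rows = genomes)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clade_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str).to_dict()


def write_regions_bed(regions: Iterable[BindingRegion], path) -> None:
    """0-based half-open BED: name = TF, score = mean window E-score x1000
    (rounded), class in column 7."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.promoter_id, r.start, r.tf)):
            score = int(round(r.mean_escore * 1000)) if r.mean_escore == r.mean_escore else 0
            fh.write(
                f"{r.promoter_id}\t{r.start}\t{r.end}\t{r.tf}\t{score}\t.\t"
                f"{r.region_class or '.'}\n"
            )
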