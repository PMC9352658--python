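"""Configuration and file I/O.

One structured YAML config governs a pipeline run; a single top-level seed
feeds every source of randomness. FASTQ input is gzip-transparent. All output
tables are TSV/CSV with a header comment declaring the column schema.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .locus import LocusReference, ReadRecord
from .simulate import DEFAULT_PLANTED_MH, SimulationConfig, make_locus

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Validated run configuration with per-stage sections."""

    seed: int = 0
    locus: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    calling: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fdr = self.classify.get("fdr", 0.10)
        if not 0.0 < fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.calling.get("anchor_length", 10) <= 0:
            raise ValueError("anchor_length must be positive")
        win = self.calling.get("artifact_window", [3, 10])
        if len(win) != 2 or win[0] < 1 or win[1] < win[0]:
            raise ValueError("artifact_window must be an increasing pair of distances >= 1")

    @property
    def fdr(self) -> float:
        return self.classify.get("fdr", 0.10)

    @property
    def anchor_length(self) -> int:
        return self.calling.get("anchor_length", 10)

    @property
    def artifact_window(self) -> tuple[int, int]:
        lo, hi = self.calling.get("artifact_window", [3, 10])
        return int(lo), int(hi)

    @property
    def calibrator(self) -> str:
        return self.classify.get("calibrator", "wt")

    def simulation_config(self, seed: Optional[int] = None) -> SimulationConfig:
        keys = {
            "n_reads",
            "event_mixture",
            "polq_null_depletion",
            "substitution_error_rate",
            "ambiguity_rate",
            "read_length",
        }
        kwargs = {k: v for k, v in self.simulate.items() if k in keys}
        planted = self.locus.get("planted_microhomologies")
        if planted is not None:
            kwargs["planted_mh"] = tuple(tuple(p) for p in planted)
        return SimulationConfig(seed=self.seed if seed is None else seed, **kwargs)


def load_config(path: PathLike) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {k: raw.get(k, {}) for k in ("locus", "simulate", "calling", "classify", "quantify")}
    return PipelineConfig(seed=int(raw.get("seed", 0)), **sections)


def locus_from_config(config: PipelineConfig) -> LocusReference:
    """Resolve the reference locus: explicit sequence, or generated from seed."""
    loc = config.locus
    if "sequence" in loc:
        seq = loc["sequence"].upper()
        plen = int(loc.get("primer_length", 20))
        return LocusReference(
            name=loc.get("name", "locus"),
            sequence=seq,
            cut_site=int(loc["cut_site"]),
            primer_fwd=loc.get("primer_fwd", seq[:plen]),
            primer_rev=loc.get("primer_rev", ""),
        )
    planted = loc.get("planted_microhomologies", DEFAULT_PLANTED_MH)
    return make_locus(
        seed=int(loc.get("seed", config.seed)),
        length=int(loc.get("length", 200)),
        planted_microhomologies=tuple(tuple(p) for p in planted),
        cut_site=loc.get("cut_site"),
        name=loc.get("name", "synthetic_locus"),
    )


def read_fastq(path: PathLike) -> list[ReadRecord]:
    """Read a FASTQ file (gzip-transparent) into ReadRecords."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTQ file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_locus_fasta(locus: LocusReference, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f">{locus.name} cut_site={locus.cut_site}\n{locus.sequence}\n")


def write_table(df: pd.DataFrame, path: PathLike, description: str = "") -> None:
    """Write a tidy table with a schema header comment."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    with open(path, "w") as fh:
        if description:
            fh.write(f"# {description}\n")
        fh.write(f"# columns: {', '.join(map(str, df.columns))}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep, comment="#", keep_default_na=False, na_values=[""])
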