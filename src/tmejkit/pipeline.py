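"""End-to-end pipeline: simulate -> call -> classify -> quantify.

Stages can be run individually (see :mod:`tmejkit.cli`) or as one bundle via
:func:`run_pipeline`, which writes every intermediate table plus a run
manifest (version, seeds, filter attrition). All randomness flows from the
single top-level seed through spawned child generators, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assays import relative_signature_table, resection_profile
from .calling import JunctionTable, call_read, tabulate_junctions
from .io import PipelineConfig, PathLike, read_fastq, write_locus_fasta, write_table
from .locus import LocusReference, ReadLayout
from .pathways import SignatureSet, build_signature, pathway_fractions, tmej_contribution, _pool
from .simulate import (
    DEFAULT_BARCODES,
    DdpcrTruth,
    simulate_ddpcr,
    simulate_qpcr,
    simulate_reads,
    write_fastq,
)

logger = logging.getLogger(__name__)


def call_fastq(
    fastq_path: PathLike,
    locus: LocusReference,
    sample_id: str,
    config: Optional[PipelineConfig] = None,
) -> JunctionTable:
    """Trim, call, and tabulate one sample's FASTQ."""
    config = config or PipelineConfig()
    layout = ReadLayout(primer=locus.primer_fwd)
    reads = read_fastq(fastq_path)
    calls = [
        call_read(
            r, locus, layout=layout, anchor_length=config.anchor_length,
            artifact_window=config.artifact_window,
        )
        for r in reads
    ]
    return tabulate_junctions(calls, sample_id=sample_id)


def pooled_table(tables: Sequence[JunctionTable], sample_id: str) -> JunctionTable:
    """Sum replicate tables into one pooled condition-level table."""
    df, total = _pool(list(tables))
    df = df[[c for c in JunctionTable.COLUMNS if c in df.columns]]
    return JunctionTable(
        sample_id=sample_id,
        df=df.reset_index(drop=True),
        intact_count=sum(t.intact_count for t in tables),
        repair_total=total,
        attrition={},
    )


def run_pipeline(config: PipelineConfig, outdir: PathLike) -> dict:
    """Execute the full demo pipeline and write all declared outputs.

    Simulates replicate wild-type and Polq-null samples, calls junctions,
    derives the TMEJ deletion signature by differential depletion, reports
    pathway fractions and percentage-point deltas against the wild-type
    calibrator, and runs the qPCR/ddPCR quantification arithmetic on
    simulated measurement tables. Returns a summary dict (also written as
    ``run_manifest.json``).
    """
    from .io import locus_from_config  # local import to keep module load light

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    locus = locus_from_config(config)
    write_locus_fasta(locus, out / "reference.fasta")

    n_replicates = int(config.simulate.get("replicates", 3))
    seedseq = np.random.SeedSequence(config.seed)
    children = seedseq.spawn(2 * n_replicates + 2)

    manifest_rows = []
    tables: dict[str, list[JunctionTable]] = {"wt": [], "polq_null": []}
    attrition_all: dict[str, dict] = {}
    idx = 0
    for condition in ("wt", "polq_null"):
        for rep in range(1, n_replicates + 1):
            sample_id = f"{condition}_rep{rep}"
            rng = np.random.default_rng(children[idx])
            idx += 1
            sim_cfg = config.simulation_config()
            reads, truth = simulate_reads(
                sim_cfg, locus, condition=condition, sample_id=sample_id, rng=rng
            )
            fastq = out / f"{sample_id}.fastq"
            write_fastq(reads, fastq)
            write_table(truth, out / f"{sample_id}.truth.tsv", "simulation ground truth per read")
            table = call_fastq(fastq, locus, sample_id, config)
            table.to_tsv(out / f"{sample_id}.junctions.tsv")
            tables[condition].append(table)
            attrition_all[sample_id] = table.attrition
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "condition": condition,
                    "replicate": rep,
                    "role": "wt_calibrator" if condition == "wt" else "polq_null",
                    "fastq": fastq.name,
                    "barcode": DEFAULT_BARCODES.get(condition, ""),
                }
            )
    write_table(pd.DataFrame(manifest_rows), out / "samples.csv", "sample manifest")

    signature = build_signature(tables["wt"], tables["polq_null"], fdr=config.fdr)
    signature.to_tsv(out / "signature.tsv")

    pooled = {
        cond: pooled_table(tabs, sample_id=cond) for cond, tabs in tables.items()
    }
    fracs = {cond: pathway_fractions(t, signature) for cond, t in pooled.items()}
    write_table(
        pd.DataFrame([f.as_dict() for f in fracs.values()]),
        out / "pathway_fractions.tsv",
        "pathway class fractions of all repair reads, per condition (replicates pooled)",
    )
    deltas = tmej_contribution(fracs, calibrator=config.calibrator)
    write_table(
        deltas, out / "pathway_deltas.tsv",
        "percentage-point class deltas relative to the calibrator condition",
    )

    # Measurement-assay arithmetic on simulated tables
    qpcr_levels = {"wt": 1.0, "polq_null": max(config.simulate.get("polq_null_depletion", 0.25), 1e-6)}
    qpcr = simulate_qpcr(qpcr_levels, calibrator="wt", seed=int(children[-2].generate_state(1)[0] % 2**31))
    write_table(qpcr, out / "qpcr_ct.csv", "simulated qPCR Ct table")
    rel = relative_signature_table(qpcr, calibrator="wt")
    write_table(rel, out / "qpcr_relative.csv", "delta-delta-Ct signature levels vs calibrator")

    ddpcr_seed = int(children[-1].generate_state(1)[0] % 2**31)
    wells = simulate_ddpcr(DdpcrTruth(), n_droplets=int(config.quantify.get("n_droplets", 20000)), seed=ddpcr_seed)
    write_table(wells, out / "ddpcr_wells.csv", "simulated ddPCR droplet counts")
    profile = resection_profile(wells)
    write_table(
        pd.DataFrame(
            [{"distance_nt": d, "ssdna_fraction": f} for d, f in profile.ssdna_by_distance.items()]
        ),
        out / "resection_profile.csv",
        "ExoI-sensitive ssDNA fraction by flank distance",
    )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "locus": {"name": locus.name, "length": len(locus.sequence), "cut_site": locus.cut_site},
        "n_replicates": n_replicates,
        "signature_size": len(signature.members),
        "fractions": {c: f.as_dict() for c, f in fracs.items()},
        "deltas": deltas.to_dict(orient="records"),
        "resection": {
            "ssdna_by_distance": profile.ssdna_by_distance,
            "broken_fraction": profile.broken_fraction,
            "deletion_fraction": profile.deletion_fraction,
        },
        "attrition": attrition_all,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return summary
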