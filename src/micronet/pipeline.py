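"""End-to-end orchestration: de -> pcit -> scan -> network -> enrich.

Each stage reads and writes flat files under an output directory and never
mutates its inputs; a manifest (JSON) records the package version, the
configuration and its hash, SHA-256 checksums of every input, and per-stage
row counts, so a rerun with the same configuration can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dge import filter_expressed, nb_wald_de, size_factors
from .enrichment import hypergeom_enrich, read_annotation
from .io import read_counts, read_fasta, read_samples, write_edges
from .network import assemble_network
from .pcit import PcitEdgeSet, expression_for_correlation, pcit_significant, pearson_matrix
from .targeting import scan_all, targeted_fraction, group_mirnas_by_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("de_mrna", "de_mirna", "pcit", "scan", "network", "enrich")


@dataclass
class PipelineConfig:
    """Inputs, outputs and thresholds for one pipeline run."""

    mrna_counts: str
    mirna_counts: str
    samples: str
    mirnas_fasta: str
    utrs_fasta: str
    outdir: str
    annotation: str | None = None
    min_total: int = 20
    mrna_fc: float = 1.5
    mirna_fc: float = 1.2
    alpha: float = 0.05
    r_mirna: float = -0.50
    r_mrna: float = 0.7
    no_pcit: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mrna_fc > 1 and self.mirna_fc > 1):
            raise ValueError("fold-change thresholds must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.r_mirna < 0:
            raise ValueError("r_mirna must be negative")
        if not 0 < self.r_mrna < 1:
            raise ValueError("r_mrna must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value configuration file (# comments allowed)."""
        values: dict[str, object] = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("min_total", "rng_seed"):
                values[key] = int(value)
            elif key in ("mrna_fc", "mirna_fc", "alpha", "r_mirna", "r_mrna"):
                values[key] = float(value)
            elif key == "no_pcit":
                values[key] = value.lower() in ("1", "true", "yes")
            else:
                values[key] = value
        return cls(**values)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to outdir/manifest.json).

    A missing or unparsable input aborts with an error naming the stage
    and file. Identical configuration and inputs reproduce identical
    outputs.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    inputs = {
        "mrna_counts": cfg.mrna_counts,
        "mirna_counts": cfg.mirna_counts,
        "samples": cfg.samples,
        "mirnas_fasta": cfg.mirnas_fasta,
        "utrs_fasta": cfg.utrs_fasta,
    }
    if cfg.annotation:
        inputs["annotation"] = cfg.annotation
    for name, path in inputs.items():
        if not Path(path).is_file():
            raise FileNotFoundError(f"input {name!r} not found: {path}")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "inputs_sha256": {name: _sha256(path) for name, path in inputs.items()},
        "stages": {},
    }

    def stage(name):
        logger.info("[%s] running", name)
        return manifest["stages"].setdefault(name, {})

    try:
        # --- differential expression, mRNA layer -----------------------
        info = stage("de_mrna")
        samples = read_samples(cfg.samples)
        mrna = filter_expressed(read_counts(cfg.mrna_counts, "mRNA"), cfg.min_total)
        mrna_factors = size_factors(mrna)
        de_mrna = nb_wald_de(mrna, samples, cfg.mrna_fc, cfg.alpha, mrna_factors)
        de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t")
        info.update(n_tested=len(de_mrna), n_de=int(de_mrna["is_de"].sum()), out="de_mrna.tsv")

        # --- differential expression, miRNA layer ----------------------
        info = stage("de_mirna")
        mirna = filter_expressed(read_counts(cfg.mirna_counts, "miRNA"), cfg.min_total)
        mirna_factors = size_factors(mirna)
        de_mirna = nb_wald_de(mirna, samples, cfg.mirna_fc, cfg.alpha, mirna_factors)
        de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t")
        info.update(n_tested=len(de_mirna), n_de=int(de_mirna["is_de"].sum()), out="de_mirna.tsv")

        de_gene_ids = de_mrna.index[de_mrna["is_de"]].tolist()
        de_mirna_ids = de_mirna.index[de_mirna["is_de"]].tolist()

        # --- joint PCIT co-expression on DE features -------------------
        info = stage("pcit")
        expr = pd.concat(
            [
                expression_for_correlation(mrna, mrna_factors).loc[de_gene_ids],
                expression_for_correlation(mirna, mirna_factors).loc[de_mirna_ids],
            ]
        )
        if len(expr) >= 2:
            r = pearson_matrix(expr)
            significant = pcit_significant(r)
        else:
            r = pd.DataFrame(1.0, index=expr.index, columns=expr.index)
            significant = pd.DataFrame(False, index=expr.index, columns=expr.index)
        pcit = PcitEdgeSet(r=r, significant=significant)
        r.to_csv(outdir / "pcit_r.tsv", sep="\t", float_format="%.6f")
        significant.astype(int).to_csv(outdir / "pcit_significant.tsv", sep="\t")
        info.update(n_nodes=len(r), n_significant=int(significant.to_numpy().sum() // 2), out="pcit_r.tsv")

        # --- seed scan of DE miRNAs against the UTRs --------------------
        info = stage("scan")
        all_mirnas = {rec.id: rec for rec in read_fasta(cfg.mirnas_fasta)}
        utrs = read_fasta(cfg.utrs_fasta)
        de_mirna_records = [all_mirnas[m] for m in de_mirna_ids if m in all_mirnas]
        matches = scan_all(de_mirna_records, utrs)
        matches.to_csv(outdir / "matches.tsv", sep="\t", index=False)
        info.update(n_mirnas=len(de_mirna_records), n_pairs=len(matches), out="matches.tsv")
        if de_gene_ids and de_mirna_records:
            seed_groups = {
                "/".join(ids): ids for ids in group_mirnas_by_seed(de_mirna_records).values()
            }
            summary = targeted_fraction(matches, de_gene_ids, seed_groups)
            summary.to_csv(outdir / "targeting_summary.tsv", sep="\t", index=False)

        # --- regulatory network assembly --------------------------------
        info = stage("network")
        net = assemble_network(
            de_mirna_ids,
            de_gene_ids,
            pcit,
            matches,
            r_max=cfg.r_mirna,
            r_min_abs=cfg.r_mrna,
            require_pcit=not cfg.no_pcit,
        )
        write_edges(net, outdir / "network.tsv")
        info.update(
            n_mirna_mrna=len(net.mirna_edges), n_mrna_mrna=len(net.mrna_edges), out="network.tsv"
        )

        # --- enrichment over the expressed-gene universe -----------------
        info = stage("enrich")
        if cfg.annotation and de_gene_ids:
            enr = hypergeom_enrich(
                de_gene_ids, read_annotation(cfg.annotation), mrna.feature_ids, cfg.alpha
            )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            info.update(n_terms=len(enr), n_enriched=int(enr["enriched"].sum()), out="enrichment.tsv")
        else:
            info.update(skipped="no annotation provided" if not cfg.annotation else "no DE genes")
    except Exception as exc:
        failed = next((s for s in reversed(STAGES) if s in manifest["stages"]), "setup")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
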