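"""Calibration and recovery studies of the pipeline on ground-truthed simulations.

These drive the same public stages a user would call, against the synthetic
generator's known truth: type-I-error calibration of the differential
expression test under a global null, and precision/recall of planted
miRNA -> target edge recovery through the full de -> pcit -> scan -> network
chain.
"""

from __future__ import annotations

import pandas as pd

from .dge import filter_expressed, nb_wald_de, size_factors
from .network import assemble_network
from .pcit import PcitEdgeSet, expression_for_correlation, pcit_significant, pearson_matrix
from .simulate import SimulationConfig, SimulationResult, simulate_experiment
from .targeting import scan_all

__all__ = ["null_calibration", "run_stages", "edge_recovery"]


def null_calibration(
    n_replicates: int = 20,
    n_features: int = 200,
    n_per_group: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I behaviour of the DE stage when nothing is planted.

    Simulates ``n_replicates`` experiments with no planted effects, runs the
    mRNA DE stage on each, and pools: the fraction of raw p-values below
    0.05 (nominal type-I error) and the fraction of features declared
    significant by BH at 0.05.
    """
    n_raw = n_bh = n_total = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_samples_per_group=n_per_group,
            n_mrna=n_features,
            n_mirna=5,
            n_de_mrna=0,
            n_de_mirna=0,
            n_targets_per_de_mirna=0,
            utr_length_range=(50, 60),
            rng_seed=seed + rep,
        )
        sim = simulate_experiment(cfg)
        table = nb_wald_de(filter_expressed(sim.mrna_counts), sim.samples, 1.5)
        n_raw += int((table.p_value < 0.05).sum())
        n_bh += int((table.p_adj < 0.05).sum())
        n_total += len(table)
    return {
        "raw_p_fraction": n_raw / n_total,
        "bh_fraction": n_bh / n_total,
        "n_tests": n_total,
    }


def run_stages(sim: SimulationResult, require_pcit: bool = True):
    """de -> pcit -> scan -> network on an in-memory simulation; returns the network."""
    mrna = filter_expressed(sim.mrna_counts)
    mirna = filter_expressed(sim.mirna_counts)
    sf_m, sf_i = size_factors(mrna), size_factors(mirna)
    de_m = nb_wald_de(mrna, sim.samples, 1.5, factors=sf_m)
    de_i = nb_wald_de(mirna, sim.samples, 1.2, factors=sf_i)
    g_ids = de_m.index[de_m.is_de].tolist()
    i_ids = de_i.index[de_i.is_de].tolist()
    expr = pd.concat(
        [
            expression_for_correlation(mrna, sf_m).loc[g_ids],
            expression_for_correlation(mirna, sf_i).loc[i_ids],
        ]
    )
    if len(expr) < 3:
        matches = scan_all([x for x in sim.mirnas if x.id in i_ids], sim.utrs)
        r = pd.DataFrame(1.0, index=expr.index, columns=expr.index)
        sig = pd.DataFrame(False, index=expr.index, columns=expr.index)
        return assemble_network(i_ids, g_ids, PcitEdgeSet(r=r, significant=sig), matches)
    r = pearson_matrix(expr)
    pcit = PcitEdgeSet(r=r, significant=pcit_significant(r))
    matches = scan_all([x for x in sim.mirnas if x.id in i_ids], sim.utrs)
    return assemble_network(i_ids, g_ids, pcit, matches, require_pcit=require_pcit)


def edge_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    planted_log2fc: float = 2.0,
    repression_strength: float = 0.9,
) -> dict[str, float]:
    """Pooled precision/recall of planted miRNA -> target edges over seeds."""
    tp = fp = fn = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_mrna=200,
            n_mirna=20,
            n_de_mrna=30,
            n_de_mirna=3,
            de_log2fc_range=(planted_log2fc, planted_log2fc),
            repression_strength=repression_strength,
            n_targets_per_de_mirna=5,
            rng_seed=seed + i,
        )
        sim = simulate_experiment(cfg)
        net = run_stages(sim)
        predicted = set(zip(net.mirna_edges.source, net.mirna_edges.target))
        truth = sim.truth.true_target_edges
        tp += len(predicted & truth)
        fp += len(predicted - truth)
        fn += len(truth - predicted)
    return {
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "n_edges_predicted": tp + fp,
        "n_edges_planted": tp + fn,
    }
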