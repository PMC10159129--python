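"""Synthetic paired mRNA/miRNA experiment generator with known ground truth.

The generator emulates the design every downstream stage expects: two
phenotype groups (H and L) of equal size with balanced sex and two batches
per group, negative-binomially distributed counts (Var = mu + alpha mu^2,
one dispersion per run), planted differential expression on both layers,
repressive miRNA -> target coupling through a shared latent abundance, and
3'UTR / mature-miRNA sequences in which every planted target carries the
regulator's reverse-complemented 7mer-m8 seed site while every non-target
UTR is rejection-sampled to be free of any planted miRNA's site.

Mature miRNAs are emitted in the RNA alphabet (ACGU) and UTRs in DNA
(ACGT), so the pipeline's U -> T normalization is exercised. Positive
planted log2 fold changes mean higher expression in the L group (H is the
reference). Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CountMatrix, SequenceRecord, write_counts, write_fasta, write_samples

__all__ = ["SimulationConfig", "GroundTruth", "SimulationResult", "simulate_experiment", "plant_seed_site", "write_simulation"]

_DNA = np.array(list("ACGT"))
_RNA = "ACGU"

#: log2-scale sd of the per-sample latent abundance noise of a regulator miRNA;
#: large enough to couple targets within groups, small enough that a planted
#: group effect stays detectable at the design's sample size
LATENT_SD = 0.4
#: log2-units swing applied to a target per unit of repression_strength
REPRESSION_SCALE = 2.0
#: attempts before rejection sampling of a seed-free UTR gives up
MAX_UTR_ATTEMPTS = 1000


@dataclass
class SimulationConfig:
    """Study-design and effect-size knobs for one synthetic experiment.

    Defaults reproduce the reference design: 10 + 10 samples, balanced sex,
    two batches per group, NB dispersion 0.05, planted log2 effects spanning
    both sides of the fold-change calling thresholds, and strong (0.9)
    repressive coupling of each planted miRNA to its targets.
    """

    n_samples_per_group: int = 10
    n_mrna: int = 300
    n_mirna: int = 40
    n_de_mrna: int = 40
    n_de_mirna: int = 4
    de_log2fc_range: tuple[float, float] = (0.2, 2.0)
    nb_dispersion: float = 0.05
    mean_expression_log_range: tuple[float, float] = (3.0, 9.0)
    repression_strength: float = 0.9
    n_targets_per_de_mirna: int = 5
    utr_length_range: tuple[int, int] = (200, 800)
    batch_effect_sd: float = 0.1
    sex_effect_sd: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_terms: int = 25
    term_size_range: tuple[int, int] = (10, 30)
    n_enriched_terms: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        if self.n_de_mrna > self.n_mrna:
            raise ValueError("n_de_mrna cannot exceed n_mrna")
        if self.n_de_mirna > self.n_mirna:
            raise ValueError("n_de_mirna cannot exceed n_mirna")
        if self.n_targets_per_de_mirna > max(self.n_de_mrna, 0):
            raise ValueError("n_targets_per_de_mirna cannot exceed n_de_mrna")
        if not 0.0 <= self.repression_strength <= 1.0:
            raise ValueError("repression_strength must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("de_log2fc_range", "mean_expression_log_range", "utr_length_range", "size_factor_range", "term_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (low <= high), got ({lo}, {hi})")
        if self.utr_length_range[0] < 1:
            raise ValueError("utr lengths must be positive")


@dataclass
class GroundTruth:
    """What was planted: consumed by recovery/calibration tests, never by the pipeline."""

    true_de_mrna: dict[str, float] = field(default_factory=dict)
    true_de_mirna: dict[str, float] = field(default_factory=dict)
    true_target_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_seed_sites: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    true_enriched_terms: set[str] = field(default_factory=set)
    negative_control_genes: set[str] = field(default_factory=set)


@dataclass
class SimulationResult:
    mrna_counts: CountMatrix
    mirna_counts: CountMatrix
    samples: pd.DataFrame
    utrs: list[SequenceRecord]
    mirnas: list[SequenceRecord]
    annotation: pd.DataFrame
    truth: GroundTruth


def plant_seed_site(utr: str, seed7: str, offset: int) -> str:
    """Overwrite utr[offset:offset+7] with the reverse complement of ``seed7``.

    ``seed7`` is a 7-nt seed in RNA or DNA alphabet; the inserted site is
    its DNA reverse complement — exactly the string the targeting scan
    searches for. Length of the UTR is unchanged.
    """
    if len(seed7) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed7)}")
    if offset < 0 or offset + 7 > len(utr):
        raise ValueError(
            f"offset {offset} out of range for a 7-nt site in a {len(utr)}-nt UTR"
        )
    site = str(Seq(seed7.upper().replace("U", "T")).reverse_complement())
    return utr[:offset] + site + utr[offset + 7 :]


def _sample_table(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group in ("H", "L"):
        for i in range(cfg.n_samples_per_group):
            rows.append(
                {
                    "sample_id": f"{group}{i + 1:02d}",
                    "group": group,
                    # alternate sex and batch within each group: balanced and
                    # unconfounded with the group contrast
                    # sex alternates sample-by-sample, batch pair-by-pair, so
                    # the two covariates are not confounded with each other
                    "sex": "M" if i % 2 == 0 else "F",
                    "batch": f"b{(i // 2) % 2 + 1}",
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return df


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


def _seed_free_utr(rng: np.random.Generator, length: int, forbidden: set[str]) -> str:
    """Random UTR containing none of the forbidden 7-nt sites."""
    for _ in range(MAX_UTR_ATTEMPTS):
        utr = _random_seq(rng, length)
        if not any(site in utr for site in forbidden):
            return utr
    raise RuntimeError(
        f"could not draw a UTR of length {length} free of the seed site(s) "
        f"{sorted(forbidden)} in {MAX_UTR_ATTEMPTS} attempts"
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 (size = 1/alpha)."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Generate one complete synthetic experiment.

    Counts are NB draws around per-sample log2 means assembled from a
    feature baseline, the planted group effect (sign convention: positive =
    higher in L), per-feature sex and batch effects, the repression latent
    for planted targets, and a per-sample library size factor. Each planted
    (miRNA, gene) edge is backed by exactly one seed site planted at a
    recorded offset; all other UTRs are guaranteed free of every planted
    miRNA's site, so the seed scan recovers the planted edges exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    samples = _sample_table(cfg)
    n_samples = len(samples)
    in_L = (samples["group"] == "L").to_numpy()
    sex_M = (samples["sex"] == "M").to_numpy()
    batch2 = (samples["batch"] == "b2").to_numpy()

    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_mrna)]
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(cfg.n_mirna)]

    # --- planted differential expression -------------------------------
    lo, hi = cfg.de_log2fc_range
    de_genes = sorted(rng.choice(cfg.n_mrna, size=cfg.n_de_mrna, replace=False))
    de_mirs = sorted(rng.choice(cfg.n_mirna, size=cfg.n_de_mirna, replace=False))
    gene_fc = {i: rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]) for i in de_genes}
    mir_fc = {i: rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]) for i in de_mirs}

    # --- target assignment: planted targets drawn from planted DE genes
    target_map: dict[int, list[int]] = {}
    pool = list(de_genes)
    rng.shuffle(pool)
    cursor = 0
    for m in de_mirs:
        if cursor + cfg.n_targets_per_de_mirna <= len(pool):
            chosen = pool[cursor : cursor + cfg.n_targets_per_de_mirna]
            cursor += cfg.n_targets_per_de_mirna
        else:  # capacity exhausted: targets may be shared between regulators
            chosen = list(rng.choice(de_genes, size=cfg.n_targets_per_de_mirna, replace=False))
        target_map[m] = chosen

    # a repressed target moves against its (first) regulator between groups
    regulator_of: dict[int, int] = {}
    for m, targets in target_map.items():
        for g in targets:
            if g not in regulator_of:
                regulator_of[g] = m
                gene_fc[g] = -np.sign(mir_fc[m]) * abs(gene_fc[g])

    # --- per-feature effect coefficients (log2 scale) ------------------
    mrna_base = rng.uniform(*cfg.mean_expression_log_range, size=cfg.n_mrna)
    mirna_base = rng.uniform(*cfg.mean_expression_log_range, size=cfg.n_mirna)
    mrna_sex = rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_mrna)
    mirna_sex = rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_mirna)
    mrna_batch = rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_mrna)
    mirna_batch = rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_mirna)
    sf_mrna = rng.uniform(*cfg.size_factor_range, size=n_samples)
    sf_mirna = rng.uniform(*cfg.size_factor_range, size=n_samples)

    # --- miRNA log2 means, with latent abundance noise for regulators --
    mirna_log2 = np.tile(mirna_base[:, None], (1, n_samples))
    for i in range(cfg.n_mirna):
        if i in mir_fc:
            mirna_log2[i, in_L] += mir_fc[i]
        mirna_log2[i] += mirna_sex[i] * sex_M + mirna_batch[i] * batch2
    latent: dict[int, np.ndarray] = {}
    for m in de_mirs:
        mirna_log2[m] += rng.normal(0.0, LATENT_SD, size=n_samples)
        v = mirna_log2[m]
        latent[m] = (v - v.mean()) / v.std()

    # --- mRNA log2 means ------------------------------------------------
    mrna_log2 = np.tile(mrna_base[:, None], (1, n_samples))
    for i in range(cfg.n_mrna):
        if i in gene_fc:
            mrna_log2[i, in_L] += gene_fc[i]
        mrna_log2[i] += mrna_sex[i] * sex_M + mrna_batch[i] * batch2
    for m, targets in target_map.items():
        for g in targets:
            mrna_log2[g] -= cfg.repression_strength * REPRESSION_SCALE * latent[m]

    mrna_counts = _nb_draw(rng, 2.0 ** mrna_log2 * sf_mrna, cfg.nb_dispersion)
    mirna_counts = _nb_draw(rng, 2.0 ** mirna_log2 * sf_mirna, cfg.nb_dispersion)

    # --- mature miRNA sequences (RNA alphabet); all seeds distinct ------
    mirna_seqs: list[str] = []
    used_seeds: set[str] = set()
    for i in range(cfg.n_mirna):
        while True:
            seq = _random_seq(rng, 22, _RNA)
            if seq[1:8] in used_seeds:
                continue
            used_seeds.add(seq[1:8])
            break
        mirna_seqs.append(seq)
    mirnas = [SequenceRecord(mirna_ids[i], mirna_seqs[i]) for i in range(cfg.n_mirna)]

    # No simulated miRNA's site may occur uninvited in any UTR: non-target
    # UTRs are clean negative controls for the whole panel, and the only
    # seed matches in the experiment are the planted ones.
    seed_of = {i: mirna_seqs[i][1:8].replace("U", "T") for i in range(cfg.n_mirna)}
    site_of = {i: str(Seq(seed_of[i]).reverse_complement()) for i in range(cfg.n_mirna)}
    forbidden = set(site_of.values())

    targets_of_gene: dict[int, list[int]] = {}
    for m, targets in target_map.items():
        for g in targets:
            targets_of_gene.setdefault(g, []).append(m)

    utrs: list[SequenceRecord] = []
    planted_sites: dict[tuple[str, str], list[int]] = {}
    for i in range(cfg.n_mrna):
        length = int(rng.integers(cfg.utr_length_range[0], cfg.utr_length_range[1] + 1))
        regulators = targets_of_gene.get(i, [])
        if not regulators:
            utrs.append(SequenceRecord(gene_ids[i], _seed_free_utr(rng, length, forbidden)))
            continue
        if length < 7 * len(regulators):
            raise RuntimeError(
                f"UTR length {length} too short to plant {len(regulators)} seed site(s)"
            )
        for _ in range(MAX_UTR_ATTEMPTS):
            utr = _seed_free_utr(rng, length, forbidden)
            offsets = sorted(rng.choice(length - 6, size=len(regulators), replace=False))
            if any(b - a < 7 for a, b in zip(offsets, offsets[1:])):
                continue
            for m, off in zip(regulators, offsets):
                utr = plant_seed_site(utr, seed_of[m], off)
            # planting may have created an uninvited site across a junction
            found = {m: [j for j in range(length - 6) if utr[j : j + 7] == site_of[m]] for m in site_of}
            expected = {m: sorted(off for mm, off in zip(regulators, offsets) if mm == m) for m in site_of}
            if found == expected:
                break
        else:
            raise RuntimeError(
                f"could not plant clean seed site(s) {sorted(site_of[m] for m in regulators)} "
                f"in a UTR of length {length} in {MAX_UTR_ATTEMPTS} attempts"
            )
        utrs.append(SequenceRecord(gene_ids[i], utr))
        for m, off in zip(regulators, offsets):
            planted_sites[(mirna_ids[m], gene_ids[i])] = planted_sites.get(
                (mirna_ids[m], gene_ids[i]), []
            ) + [int(off)]

    # --- annotation with planted enriched terms -------------------------
    ann_rows = []
    enriched_terms: set[str] = set()
    de_gene_ids = [gene_ids[i] for i in de_genes]
    for t in range(cfg.n_terms):
        term = f"term{t + 1:03d}"
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        if t < cfg.n_enriched_terms and cfg.n_de_mrna > 0:
            enriched_terms.add(term)
            n_de_members = min(len(de_gene_ids), max(int(round(0.7 * size)), 1))
            members = list(rng.choice(de_gene_ids, size=n_de_members, replace=False))
            others = sorted(set(gene_ids) - set(members))
            members += list(rng.choice(others, size=size - n_de_members, replace=False))
        else:
            members = list(rng.choice(gene_ids, size=size, replace=False))
        ann_rows.extend({"gene_id": g, "term_id": term} for g in sorted(members))
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "term_id"])

    truth = GroundTruth(
        true_de_mrna={gene_ids[i]: float(fc) for i, fc in sorted(gene_fc.items())},
        true_de_mirna={mirna_ids[i]: float(fc) for i, fc in sorted(mir_fc.items())},
        true_target_edges={(mirna_ids[m], gene_ids[g]) for m, tg in target_map.items() for g in tg},
        planted_seed_sites=planted_sites,
        true_enriched_terms=enriched_terms,
        negative_control_genes={gene_ids[i] for i in range(cfg.n_mrna) if i not in targets_of_gene},
    )
    return SimulationResult(
        mrna_counts=CountMatrix(
            pd.DataFrame(mrna_counts, index=gene_ids, columns=samples.index), layer="mRNA"
        ),
        mirna_counts=CountMatrix(
            pd.DataFrame(mirna_counts, index=mirna_ids, columns=samples.index), layer="miRNA"
        ),
        samples=samples,
        utrs=utrs,
        mirnas=mirnas,
        annotation=annotation,
        truth=truth,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write every component of a simulation to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "samples": outdir / "samples.tsv",
        "utrs": outdir / "utrs.fa",
        "mirnas": outdir / "mature_mirnas.fa",
        "annotation": outdir / "annotation.tsv",
        "truth_de_mrna": outdir / "truth_de_mrna.tsv",
        "truth_de_mirna": outdir / "truth_de_mirna.tsv",
        "truth_edges": outdir / "truth_edges.tsv",
        "truth_seed_sites": outdir / "truth_seed_sites.tsv",
        "truth_terms": outdir / "truth_terms.tsv",
    }
    write_counts(result.mrna_counts, paths["mrna_counts"])
    write_counts(result.mirna_counts, paths["mirna_counts"])
    write_samples(result.samples, paths["samples"])
    write_fasta(result.utrs, paths["utrs"])
    write_fasta(result.mirnas, paths["mirnas"])
    result.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    t = result.truth
    pd.DataFrame(sorted(t.true_de_mrna.items()), columns=["gene_id", "log2fc"]).to_csv(
        paths["truth_de_mrna"], sep="\t", index=False
    )
    pd.DataFrame(sorted(t.true_de_mirna.items()), columns=["mirna_id", "log2fc"]).to_csv(
        paths["truth_de_mirna"], sep="\t", index=False
    )
    pd.DataFrame(sorted(t.true_target_edges), columns=["mirna_id", "gene_id"]).to_csv(
        paths["truth_edges"], sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"mirna_id": m, "gene_id": g, "offsets": ",".join(map(str, sorted(offs)))}
            for (m, g), offs in sorted(t.planted_seed_sites.items())
        ],
        columns=["mirna_id", "gene_id", "offsets"],
    ).to_csv(paths["truth_seed_sites"], sep="\t", index=False)
    pd.DataFrame(sorted(t.true_enriched_terms), columns=["term_id"]).to_csv(
        paths["truth_terms"], sep="\t", index=False
    )
    return paths
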