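"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes is generated here so each downstream stage
can be tested against known truth:

* an RNA-seq count study (negative-binomial counts, two-source batch offsets,
  a planted set of differential genes with fixed log2 effect size),
* a sparse non-negative latent loading matrix whose "active" columns load on
  the planted differential genes,
* a drug x gene perturbation reference (modified-z-score style) containing
  planted "reverser" drugs whose profiles negate the planted disease signal,
* drug annotations (trial membership, targets, fingerprints) and a viability
  table, both enriched for the planted reversers.

One RNG stream per artifact is split from the master seed, so e.g. changing
``n_drugs`` never perturbs the simulated counts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import ExpressionStudy

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_expression_study",
    "simulate_latent_loadings",
    "simulate_perturbation_reference",
    "write_study",
]

# fixed spawn keys: one stream per artifact
_KEY_PLANT, _KEY_COUNTS, _KEY_LOADINGS, _KEY_PERTURB, _KEY_ANNOT = range(5)

DISEASE = "disease"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe a mid-sized two-source tumor/control cohort (40 + 40
    samples, 2000 genes, 5% truly differential at |log2FC| = 2, NB dispersion
    0.1) with a 50-LV sparse loading matrix (3 condition-associated LVs) and a
    60-drug single-cell-line perturbation reference containing 5 planted
    reversers at |z| = 4 whose annotations are enriched at odds ratio 8.
    """

    n_genes: int = 2000
    n_tumor: int = 40
    n_control: int = 40
    n_databases: int = 2
    frac_de: float = 0.05
    lfc_scale: float = 2.0
    nb_dispersion: float = 0.1
    n_lvs: int = 50
    lv_sparsity: float = 0.04
    n_active_lvs: int = 2
    n_drugs: int = 60
    n_reversers: int = 8
    reverser_strength: float = 4.0
    annot_enrichment: float = 16.0
    seed: int = 0
    # secondary knobs (not part of the core contract)
    n_cell_lines: int = 10
    n_fp_bits: int = 128
    trial_base_rate: float = 0.25
    sensitive_base_rate: float = 0.2
    db_offset_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_tumor", "n_control", "n_databases", "n_lvs",
            "n_active_lvs", "n_drugs", "n_cell_lines", "n_fp_bits",
        ):
            if getattr(self, name) < 1 and not (
                name in ("n_active_lvs", "n_reversers") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.n_reversers < 0 or self.n_reversers > self.n_drugs:
            raise ValueError("need 0 <= n_reversers <= n_drugs")
        if self.n_active_lvs > self.n_lvs:
            raise ValueError("n_active_lvs must be <= n_lvs")
        for name in ("frac_de", "lv_sparsity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted truth: differential genes, active LVs, reverser drugs."""

    de_genes: set = field(default_factory=set)
    de_signs: dict = field(default_factory=dict)   # gene -> +1/-1 (sign of log2FC)
    active_lvs: set = field(default_factory=set)
    reverser_drugs: set = field(default_factory=set)

    def to_json(self) -> str:
        d = {
            "de_genes": sorted(self.de_genes),
            "de_signs": {k: int(v) for k, v in sorted(self.de_signs.items())},
            "active_lvs": sorted(self.active_lvs),
            "reverser_drugs": sorted(self.reverser_drugs),
        }
        return json.dumps(d, indent=1)


def _streams(config: SimConfig) -> dict[int, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(5)
    return {k: np.random.default_rng(children[k]) for k in range(5)}


def gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"G{i:0{width}d}" for i in range(config.n_genes)]


def drug_ids(config: SimConfig) -> list[str]:
    return [f"drug{i:03d}" for i in range(config.n_drugs)]


def _plant_de(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic planted-DE choice shared by all generators.

    Returns (indices of DE genes, per-DE-gene sign in {-1, +1}).
    """
    rng = _streams(config)[_KEY_PLANT]
    n_de = int(np.ceil(config.frac_de * config.n_genes))
    idx = rng.choice(config.n_genes, size=n_de, replace=False)
    # exactly balanced up/down effects (randomly assigned to genes)
    signs = rng.permutation(
        np.r_[np.ones(n_de - n_de // 2), -np.ones(n_de // 2)]
    )
    return np.sort(idx), signs[np.argsort(idx)]


def simulate_expression_study(
    config: SimConfig,
) -> tuple[ExpressionStudy, GroundTruth]:
    """NB count study with planted DE genes and additive database offsets."""
    genes = gene_ids(config)
    de_idx, de_signs = _plant_de(config)
    rng = _streams(config)[_KEY_COUNTS]

    n = config.n_tumor + config.n_control
    condition = np.r_[np.ones(config.n_tumor, int), np.zeros(config.n_control, int)]
    # round-robin database assignment within each condition (avoids confounding)
    database = np.empty(n, dtype=object)
    for cond in (1, 0):
        pos = np.flatnonzero(condition == cond)
        for j, s in enumerate(pos):
            database[s] = f"db{j % config.n_databases}"

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    beta = np.zeros(config.n_genes)
    beta[de_idx] = de_signs * config.lfc_scale
    # per-gene additive log2 offsets per non-reference database
    db_offsets = np.zeros((config.n_genes, config.n_databases))
    if config.n_databases > 1:
        db_offsets[:, 1:] = rng.normal(
            0.0, config.db_offset_sd, size=(config.n_genes, config.n_databases - 1)
        )
    db_index = np.array([int(d[2:]) for d in database])
    log2_mu = (
        np.log2(base_mean)[:, None]
        + beta[:, None] * condition[None, :]
        + db_offsets[:, db_index]
    )
    mu = 2.0**log2_mu
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    lengths = np.exp(rng.uniform(np.log(0.5), np.log(10.0), size=config.n_genes))
    samples = [f"S{i:03d}" for i in range(n)]
    study = ExpressionStudy(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, name="length_kb"),
        condition=pd.Series(condition, index=samples, name="condition"),
        database=pd.Series(database, index=samples, name="database"),
    )
    truth = GroundTruth(
        de_genes={genes[i] for i in de_idx},
        de_signs={genes[i]: int(s) for i, s in zip(de_idx, de_signs)},
    )
    return study, truth


def simulate_latent_loadings(config: SimConfig) -> tuple[pd.DataFrame, set]:
    """Sparse non-negative loading matrix; returns (Z, active LV ids).

    Each column has exactly ceil(lv_sparsity * n_genes) nonzero |N(0,1)|
    weights.  The first ``n_active_lvs`` LV supports are drawn preferentially
    from planted DE genes of a single fold-change sign (alternating across
    active LVs) so their projected activity separates the conditions.
    """
    genes = gene_ids(config)
    de_idx, de_signs = _plant_de(config)
    rng = _streams(config)[_KEY_LOADINGS]
    k = int(np.ceil(config.lv_sparsity * config.n_genes))
    if k < 1:
        raise ValueError("lv_sparsity too small: empty loading columns")
    Z = np.zeros((config.n_genes, config.n_lvs))
    pos_de = de_idx[de_signs > 0]
    neg_de = de_idx[de_signs < 0]
    # same-sign active LVs take disjoint slices of the DE pool: shared support
    # would make their loading columns collinear and split the planted effect
    n_even = (config.n_active_lvs + 1) // 2
    n_odd = config.n_active_lvs // 2
    pos_chunks = np.array_split(rng.permutation(pos_de), max(n_even, 1))
    neg_chunks = np.array_split(rng.permutation(neg_de), max(n_odd, 1))
    pools: list[np.ndarray] = []
    for j in range(config.n_active_lvs):
        chunk = pos_chunks[j // 2] if j % 2 == 0 else neg_chunks[j // 2]
        if chunk.size == 0:
            chunk = de_idx
        pools.append(np.sort(chunk))
    for j in range(config.n_lvs):
        if j < config.n_active_lvs:
            pool = pools[j]
            n_sig = min(k, pool.size) if pool.size else 0
            support = list(rng.choice(pool, size=n_sig, replace=False))
            rest = np.setdiff1d(np.arange(config.n_genes), support)
            if k - n_sig > 0:
                support += list(rng.choice(rest, size=k - n_sig, replace=False))
            support = np.array(support)
        else:
            support = rng.choice(config.n_genes, size=k, replace=False)
        Z[support, j] = np.abs(rng.normal(size=k))
    lv_ids = [f"LV{j:02d}" for j in range(config.n_lvs)]
    active = set(lv_ids[: config.n_active_lvs])
    return pd.DataFrame(Z, index=genes, columns=lv_ids), active


def _odds_boost(p0: float, odds_ratio: float) -> float:
    odds = p0 / (1.0 - p0) * odds_ratio
    return odds / (1.0 + odds)


def simulate_perturbation_reference(
    config: SimConfig,
    truth: GroundTruth,
    study: ExpressionStudy,
) -> tuple["PerturbationReference", "DrugAnnotations", "ViabilityTable"]:
    """Drug x gene z-score reference plus reverser-enriched annotations.

    Reverser drugs get z = -reverser_strength * sign(true log2FC) + noise on
    the planted DE genes; everything else is standard-normal noise.  Trial
    membership and screen sensitivity are Bernoulli with reverser odds
    multiplied by ``annot_enrichment``; reverser fingerprints share a common
    set block in the first quarter of the bit vector.
    """
    from .reversion import PerturbationReference      # local: avoid cycle
    from .benchmarks import DrugAnnotations, ViabilityTable

    genes = list(study.gene_ids)
    if set(truth.de_genes) - set(genes):
        raise ValueError("ground truth genes not in the study gene universe")
    rngs = _streams(config)
    rng = rngs[_KEY_PERTURB]
    drugs = drug_ids(config)
    reversers = set(drugs[: config.n_reversers])

    Z = rng.normal(size=(config.n_drugs, len(genes)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    de_cols = np.array([gene_pos[g] for g in sorted(truth.de_genes)], dtype=int)
    de_sign = np.array([truth.de_signs[g] for g in sorted(truth.de_genes)])
    for d in range(config.n_reversers):
        Z[d, de_cols] += -config.reverser_strength * de_sign
    ref = PerturbationReference(
        zmat=pd.DataFrame(Z, index=drugs, columns=genes),
        cell_line="SIMLINE",
    )

    rng_a = rngs[_KEY_ANNOT]
    p_trial = config.trial_base_rate
    p_trial_rev = _odds_boost(p_trial, config.annot_enrichment)
    in_trial = {}
    targets = {}
    moas = {}
    fps = {}
    moa_vocab = [f"moa_{c}" for c in "ABCDEFGH"]
    shared_target = genes[int(rng_a.integers(len(genes)))]
    block = config.n_fp_bits // 4
    for d in drugs:
        is_rev = d in reversers
        in_trial[d] = {
            DISEASE: bool(rng_a.random() < (p_trial_rev if is_rev else p_trial))
        }
        tg = set(rng_a.choice(genes, size=int(rng_a.integers(1, 4)), replace=False))
        if is_rev:
            tg.add(shared_target)
        targets[d] = tg
        moas[d] = moa_vocab[int(rng_a.integers(len(moa_vocab)))]
        fp = rng_a.random(config.n_fp_bits) < 0.25
        if is_rev:
            fp[:block] = True
        fps[d] = fp
    annotations = DrugAnnotations(
        drug_ids=list(drugs),
        fda_approved={d: True for d in drugs},
        in_trial=in_trial,
        targets=targets,
        moa=moas,
        fingerprints=fps,
    )

    p_sens = config.sensitive_base_rate
    p_sens_rev = _odds_boost(p_sens, config.annot_enrichment)
    lines = [f"CL{i:02d}" for i in range(config.n_cell_lines)]
    viab = np.empty((config.n_drugs, config.n_cell_lines))
    for i, d in enumerate(drugs):
        is_rev = d in reversers
        sens_drug = rng_a.random() < (p_sens_rev if is_rev else p_sens)
        if sens_drug:
            viab[i] = rng_a.normal(0.0, 0.15, size=config.n_cell_lines)
        else:
            viab[i] = rng_a.normal(0.8, 0.25, size=config.n_cell_lines)
    vtable = ViabilityTable(
        values=pd.DataFrame(viab, index=drugs, columns=lines),
        disease_of_line={ln: DISEASE for ln in lines},
    )
    truth.reverser_drugs = reversers
    return ref, annotations, vtable


def write_study(
    outdir: str | Path,
    study: ExpressionStudy,
    truth: GroundTruth,
    loadings: pd.DataFrame | None = None,
    ref=None,
    annotations=None,
    vtable=None,
) -> None:
    """Write all simulated artifacts as plain-text files under ``outdir``."""
    from . import io as sio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.counts.to_csv(out / "counts.tsv", sep="\t")
    meta = pd.DataFrame(
        {"condition": study.condition, "database": study.database}
    )
    meta.index.name = "sample_id"
    meta.to_csv(out / "samples.tsv", sep="\t")
    study.gene_lengths.rename("length_kb").to_frame().rename_axis("gene_id").to_csv(
        out / "gene_lengths.tsv", sep="\t"
    )
    (out / "ground_truth.json").write_text(truth.to_json())
    if loadings is not None:
        loadings.rename_axis("gene_id").to_csv(out / "loadings.tsv", sep="\t")
    if ref is not None:
        sio.write_gct(out / "perturbation_reference.gct", ref.zmat)
    if annotations is not None:
        annotations.to_frame().to_csv(out / "annotations.tsv", sep="\t")
        with open(out / "fingerprints.tsv", "w") as fh:
            fh.write("drug_id\tfingerprint_hex\n")
            for d in annotations.drug_ids:
                bits = annotations.fingerprints[d]
                fh.write(f"{d}\t{sio.bits_to_hex(bits)}\n")
    if vtable is not None:
        vtable.values.rename_axis("drug_id").to_csv(out / "viability.tsv", sep="\t")
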