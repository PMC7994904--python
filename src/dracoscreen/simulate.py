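"""Synthetic pooled-screen and viability-plate generation.

The generator emulates the count structure of a GeCKOv2-style dropout
screen so the whole analysis pipeline can be exercised against known
ground truth:

* a library of genes with six guides each plus non-targeting controls,
  baseline abundances drawn log-normally (library composition bias);
* heterogeneous per-guide editing efficiency: a fraction of guides is
  inactive, the rest draw a Beta-distributed efficiency — the reason
  sign-concordance filtering exists;
* per-gene fitness effects: a basal knockout fitness f_g (essential
  genes deplete in every arm) and a drug-interaction effect d_g that
  only acts under drug pressure;
* escalating drug pressure over three post-baseline timepoints,
  mirroring a screen design in which drug concentration is stepped up
  so resistant populations are selected gradually;
* negative-binomial (Gamma-Poisson) sequencing counts at a target
  coverage of >= 500 reads per guide.

Cell abundance evolves multiplicatively between collections:

    a_i(t+1) = a_i(t) * exp(e_i * (f_g + p(t) * d_g))

with guide efficiency e_i, arm pressure p(t) (vehicle arms have p=0)
and counts drawn around depth-scaled relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .screen_io import CountTable, GuideLibrary, GuideRecord, SampleInfo

LABEL_NULL = "null"
LABEL_STRONG_DROPOUT = "strong_dropout"
LABEL_STRONG_ENRICHMENT = "strong_enrichment"
LABEL_SINGLE_EFFICIENT = "single_efficient_guide"
LABEL_ESSENTIAL = "essential"
CONTROL_GENE = "CTRL"

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults describe a desk-scale screen: 2,000 genes x 6 guides at
    500x coverage with a three-step escalating pressure schedule, 30
    strong drug-dropout genes (>= 4 efficient guides each), 10 genes
    carrying a single hyper-efficient guide (the false-positive mode
    the four-of-six filter exists to reject), 10 strong enrichment
    genes, and 50 basally essential genes for the editing-efficiency
    CDF diagnostic.
    """

    n_genes: int = 2000
    guides_per_gene: int = 6
    n_control_guides: int = 100
    spacer_length: int = 20

    baseline_sigma: float = 0.8          # lognormal sd of library composition
    depth_per_guide: float = 500.0       # target sequencing coverage per guide
    dispersion: float = 0.2              # NB dispersion alpha (var = mu + alpha*mu^2)

    frac_inactive: float = 0.2           # guides with no editing activity
    efficiency_alpha: float = 5.0        # Beta(alpha, beta) for active guides
    efficiency_beta: float = 2.0

    n_strong_dropout: int = 30
    n_single_efficient: int = 10
    n_strong_enrichment: int = 10
    n_essential: int = 50
    dropout_effect: float = -1.0         # d_g, per unit pressure (natural log scale)
    enrichment_effect: float = 1.0
    essential_fitness: float = -0.4      # f_g per collection interval

    pressure_schedule: tuple[float, ...] = (0.5, 1.0, 2.0)  # T1, T2, T3
    seed: int = 0

    def validate(self) -> None:
        if self.guides_per_gene < 1:
            raise ParameterError("guides_per_gene must be >= 1")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.depth_per_guide <= 0:
            raise ParameterError("depth_per_guide must be > 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if not 0 <= self.frac_inactive <= 1:
            raise ParameterError("frac_inactive must be in [0, 1]")
        n_labeled = (
            self.n_strong_dropout
            + self.n_single_efficient
            + self.n_strong_enrichment
            + self.n_essential
        )
        if n_labeled > self.n_genes:
            raise ParameterError("labeled genes exceed n_genes")


@dataclass
class GroundTruth:
    """Per-gene effects/labels and per-guide efficiencies."""

    genes: pd.DataFrame    # index gene: label, d_g, f_g
    guides: pd.DataFrame   # index guide_id: gene, efficiency

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.genes.index[self.genes["label"] == label])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.genes.to_csv(path.with_suffix(".genes.tsv"), sep="\t")
        self.guides.to_csv(path.with_suffix(".guides.tsv"), sep="\t")


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_library(
    config: SimConfig, seed: int | None = None
) -> tuple[GuideLibrary, GroundTruth]:
    """Generate a guide library with ground-truth labels and effects."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_genes, gpg = config.n_genes, config.guides_per_gene
    width = max(4, len(str(n_genes)))
    gene_names = [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]

    order = rng.permutation(n_genes)
    labels = np.full(n_genes, LABEL_NULL, dtype=object)
    pos = 0
    for label, count in (
        (LABEL_STRONG_DROPOUT, config.n_strong_dropout),
        (LABEL_SINGLE_EFFICIENT, config.n_single_efficient),
        (LABEL_STRONG_ENRICHMENT, config.n_strong_enrichment),
        (LABEL_ESSENTIAL, config.n_essential),
    ):
        labels[order[pos : pos + count]] = label
        pos += count

    d_g = np.zeros(n_genes)
    f_g = np.zeros(n_genes)
    d_g[labels == LABEL_STRONG_DROPOUT] = config.dropout_effect
    d_g[labels == LABEL_SINGLE_EFFICIENT] = config.dropout_effect
    d_g[labels == LABEL_STRONG_ENRICHMENT] = config.enrichment_effect
    f_g[labels == LABEL_ESSENTIAL] = config.essential_fitness

    def draw_mixture(size: int) -> np.ndarray:
        eff = rng.beta(config.efficiency_alpha, config.efficiency_beta, size=size)
        eff[rng.random(size) < config.frac_inactive] = 0.0
        return eff

    records: list[GuideRecord] = []
    eff_rows: list[tuple[str, str, float]] = []
    n_guides_total = n_genes * gpg + config.n_control_guides
    spacers = _random_spacers(rng, n_guides_total, config.spacer_length)
    si = 0
    for gi, gene in enumerate(gene_names):
        eff = draw_mixture(gpg)
        label = labels[gi]
        if label in (LABEL_STRONG_DROPOUT, LABEL_STRONG_ENRICHMENT):
            # guarantee at least four efficient guides
            n_force = min(4, gpg)
            eff[:n_force] = rng.beta(
                config.efficiency_alpha, config.efficiency_beta, size=n_force
            )
        elif label == LABEL_SINGLE_EFFICIENT:
            eff[:] = 0.0
            eff[0] = 1.0
        for j in range(gpg):
            gid = f"{gene}_sg{j + 1}"
            records.append(GuideRecord(gid, spacers[si], gene))
            eff_rows.append((gid, gene, float(eff[j])))
            si += 1
    for c in range(1, config.n_control_guides + 1):
        gid = f"{CONTROL_GENE}_sg{c}"
        records.append(GuideRecord(gid, spacers[si], CONTROL_GENE, is_control=True))
        eff_rows.append((gid, CONTROL_GENE, 0.0))
        si += 1

    genes_df = pd.DataFrame(
        {"label": labels, "d_g": d_g, "f_g": f_g},
        index=pd.Index(gene_names, name="gene"),
    )
    guides_df = pd.DataFrame(
        eff_rows, columns=["guide_id", "gene", "efficiency"]
    ).set_index("guide_id")
    library = GuideLibrary(
        records, guides_per_gene=gpg, spacer_length=config.spacer_length
    )
    return library, GroundTruth(genes=genes_df, guides=guides_df)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    mu = np.clip(mu, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_screen(
    library: GuideLibrary,
    truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> CountTable:
    """Simulate counts for two T0 replicates plus vehicle/drug arms.

    Samples (in column order): ``T0_r1, T0_r2`` (baseline replicates),
    then ``VEH_Tk`` and ``DRUG_Tk`` for each post-baseline timepoint of
    the pressure schedule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    gids = library.guide_ids
    n = len(gids)
    genes = truth.guides.loc[gids, "gene"].to_numpy()
    eff = truth.guides.loc[gids, "efficiency"].to_numpy(float)
    d = truth.genes["d_g"].reindex(genes).fillna(0.0).to_numpy(float)
    f = truth.genes["f_g"].reindex(genes).fillna(0.0).to_numpy(float)

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    depth = config.depth_per_guide * n

    samples: list[SampleInfo] = [
        SampleInfo("T0_r1", "baseline", "T0", 1),
        SampleInfo("T0_r2", "baseline", "T0", 2),
    ]
    abundances: dict[str, np.ndarray] = {}
    a_vehicle = baseline.copy()
    a_drug = baseline.copy()
    timepoints = [f"T{i}" for i in range(1, len(config.pressure_schedule) + 1)]
    for tp, pressure in zip(timepoints, config.pressure_schedule):
        a_vehicle = a_vehicle * np.exp(eff * f)
        a_drug = a_drug * np.exp(eff * (f + pressure * d))
        abundances[f"VEH_{tp}"] = a_vehicle.copy()
        abundances[f"DRUG_{tp}"] = a_drug.copy()
        samples.append(SampleInfo(f"VEH_{tp}", "vehicle", tp, 1))
        samples.append(SampleInfo(f"DRUG_{tp}", "drug_A", tp, 1))

    columns: dict[str, np.ndarray] = {}
    for s in samples[:2]:
        mu = baseline / baseline.sum() * depth
        columns[s.sample_id] = _nb_counts(rng, mu, config.dispersion)
    for s in samples[2:]:
        a = abundances[s.sample_id]
        mu = a / a.sum() * depth
        columns[s.sample_id] = _nb_counts(rng, mu, config.dispersion)

    counts = pd.DataFrame(
        {s.sample_id: columns[s.sample_id] for s in samples},
        index=pd.Index(gids, name="guide_id"),
        dtype=np.int64,
    )
    return CountTable(counts, samples)


def simulate_screen_dataset(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[GuideLibrary, GroundTruth, CountTable]:
    """Convenience: library + truth + counts in one call."""
    config = config or SimConfig()
    library, truth = simulate_library(config, seed=seed)
    counts = simulate_screen(
        library, truth, config, seed=None if seed is None else seed + 1
    )
    return library, truth, counts


def simulate_plate(
    true_killing: dict[str, float],
    replicate_cv: float = 0.05,
    n_replicates: int = 4,
    seed: int = 0,
    blank_absorbance: float = 0.1,
    vehicle_signal: float = 1.0,
    n_blank: int = 4,
    n_vehicle: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a 96-well MTS plate from known per-condition killing.

    `true_killing` maps treatment labels to killing percentages in
    [0, 100] (vehicle wells, killing 0, are added automatically). Each
    well reads ``blank + vehicle_signal * (1 - killing/100) * noise``
    with multiplicative Gaussian noise of coefficient `replicate_cv`;
    at cv=0 the analysis recovers the true viabilities exactly.

    Returns ``(reads, layout)`` long-format DataFrames compatible with
    :func:`dracoscreen.combo.compute_viability`.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if replicate_cv < 0:
        raise ParameterError("replicate_cv must be >= 0")
    for cond, k in true_killing.items():
        if not 0 <= k <= 100:
            raise ParameterError(f"killing for {cond!r} must be in [0, 100]")
    rng = np.random.default_rng(seed)
    n_vehicle = n_replicates if n_vehicle is None else n_vehicle
    conditions = (
        [("blank", None)] * n_blank
        + [("vehicle", 0.0)] * n_vehicle
        + [(c, k) for c, k in true_killing.items() for _ in range(n_replicates)]
    )
    if len(conditions) > 96:
        raise ParameterError("plate overflows 96 wells; reduce conditions/replicates")
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    rows_reads, rows_layout = [], []
    for well, (cond, killing) in zip(wells, conditions):
        noise = 1.0 + replicate_cv * rng.standard_normal()
        if cond == "blank":
            absorbance = blank_absorbance * (1.0 + replicate_cv * rng.standard_normal())
        else:
            absorbance = blank_absorbance + vehicle_signal * (1.0 - killing / 100.0) * noise
        rows_reads.append({"well": well, "absorbance": absorbance})
        rows_layout.append({"well": well, "condition": cond})
    return pd.DataFrame(rows_reads), pd.DataFrame(rows_layout)
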