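"""Synthetic data generators with planted, scoreable structure.

Expression follows a Gaussian latent-factor model: each planted module m
has a latent profile f_m over samples, member genes are a_g * f_m + noise,
background genes are independent noise, and planted regulators are
(+/-) f_m plus small noise. A negative-binomial layer converts profiles to
counts where integer matrices are required. Phenotype vectors are built
from planted gene profiles with noise calibrated to a target correlation.
All generators are deterministic under a fixed seed and return truth
tables sufficient to score module recovery, regulator ranking, phenotype
flagging, and homology tier assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from secrepath.catalogue import Catalogue, Component, save_catalogue
from secrepath.network import Interaction, save_interactions


class SimulationError(ValueError):
    """Raised on invalid synthetic-data specifications."""


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    loading_range: tuple[float, float] = (0.8, 1.2)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic expression generator."""

    n_genes: int = 1000
    n_samples: int = 24
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(25)] * 4
    )
    noise_sd: float = 0.3
    n_regulators_per_module: int = 0
    n_anti_regulators_per_module: int = 0
    regulator_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        planted = sum(m.size for m in self.modules) + len(self.modules) * (
            self.n_regulators_per_module + self.n_anti_regulators_per_module
        )
        if planted > self.n_genes:
            raise SimulationError("module sizes and regulators exceed n_genes")
        if self.noise_sd < 0 or self.regulator_noise_sd < 0:
            raise SimulationError("noise sd must be >= 0")
        if self.n_samples < 1 or self.n_genes < 1:
            raise SimulationError("n_genes and n_samples must be >= 1")


def generate_modular_expression(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) plus a truth table.

    Truth columns: ``role`` in {module, regulator, anti_regulator,
    background} and ``module`` (module index or -1).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples = [f"s{j:02d}" for j in range(spec.n_samples)]
    values = np.empty((spec.n_genes, spec.n_samples))
    role = np.full(spec.n_genes, "background", dtype=object)
    module_of = np.full(spec.n_genes, -1)

    cursor = 0
    for m, mod in enumerate(spec.modules):
        latent = rng.standard_normal(spec.n_samples)
        loadings = rng.uniform(*mod.loading_range, size=mod.size)
        block = loadings[:, None] * latent[None, :] + rng.normal(
            0.0, spec.noise_sd, size=(mod.size, spec.n_samples)
        )
        values[cursor : cursor + mod.size] = block
        role[cursor : cursor + mod.size] = "module"
        module_of[cursor : cursor + mod.size] = m
        cursor += mod.size
        for _ in range(spec.n_regulators_per_module):
            values[cursor] = latent + rng.normal(
                0.0, spec.regulator_noise_sd, size=spec.n_samples
            )
            role[cursor] = "regulator"
            module_of[cursor] = m
            cursor += 1
        for _ in range(spec.n_anti_regulators_per_module):
            values[cursor] = -latent + rng.normal(
                0.0, spec.regulator_noise_sd, size=spec.n_samples
            )
            role[cursor] = "anti_regulator"
            module_of[cursor] = m
            cursor += 1

    n_background = spec.n_genes - cursor
    values[cursor:] = rng.standard_normal((n_background, spec.n_samples))

    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = pd.DataFrame({"role": role, "module": module_of}, index=genes)
    return expr, truth


def generate_counts(
    spec: SyntheticSpec,
    *,
    dispersion: float = 0.1,
    library_size_range: tuple[float, float] = (5e5, 2e6),
    base_log2_mean: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix derived from the expression model.

    Gene-wise relative abundances come from exponentiating the latent
    expression profiles; per-sample library sizes are drawn uniformly from
    ``library_size_range``; counts are NB with common ``dispersion``
    (Poisson in the dispersion -> 0 limit).
    """
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    expr, truth = generate_modular_expression(spec)
    rng = np.random.default_rng(spec.seed + 1)
    rel = 2.0 ** (expr.to_numpy() + base_log2_mean)
    rel /= rel.sum(axis=0, keepdims=True)
    lib = rng.uniform(*library_size_range, size=spec.n_samples)
    mu = rel * lib[None, :]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=expr.index, columns=expr.columns
    )
    return counts_df, truth


def generate_phenotype(
    expr: pd.DataFrame,
    plants: dict[str, float],
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Phenotype vector correlated with planted genes at target strengths.

    ``plants`` maps gene id -> target correlation in [-1, 1]. The
    phenotype is the sign-weighted sum of the standardised planted
    profiles plus Gaussian noise whose variance is calibrated so the
    realised correlation approximates the (largest-magnitude) target.
    With a single plant at target rho and no competing plants, the noise
    sd is sd(signal) * sqrt(1/rho^2 - 1).
    """
    missing = [g for g in plants if g not in expr.index]
    if missing:
        raise SimulationError(f"planted genes absent from matrix: {missing}")
    rng = np.random.default_rng(seed)
    n_samples = expr.shape[1]
    if plants:
        signal = np.zeros(n_samples)
        for gene, target in plants.items():
            profile = expr.loc[gene].to_numpy(dtype=float)
            sd = profile.std()
            if sd == 0:
                raise SimulationError(f"planted gene {gene} is constant")
            signal += np.sign(target) * (profile - profile.mean()) / sd
        top = max(abs(t) for t in plants.values())
        if top >= 1.0:
            noise_sd = 0.0
        else:
            noise_sd = signal.std() * np.sqrt(1.0 / top**2 - 1.0)
        phenotype = signal + rng.normal(0.0, noise_sd, size=n_samples)
    else:
        phenotype = rng.standard_normal(n_samples)
    truth = pd.DataFrame(
        {"gene": list(plants), "target_rho": list(plants.values())}
    )
    return pd.Series(phenotype, index=expr.columns, name="phenotype"), truth


def generate_toy_recon(
    n_components: int = 20,
    n_complexes: int = 2,
    n_groups: int = 3,
    *,
    interaction_density: float = 0.1,
    tier_mix: tuple[float, float, float] = (0.7, 0.2, 0.1),
    species: str = "mouse",
    seed: int = 0,
) -> tuple[Catalogue, list[Interaction], pd.DataFrame]:
    """Toy catalogue, interaction list, and alignment hit table.

    Components are spread round-robin over subsystems, complexes, and
    functional groups. Random undirected protein-protein interactions are
    added at the requested density. The hit table (12-column tabular plus
    partial/pseudogene flag columns) is constructed so that each reference
    lands in the high / moderate / unmapped tier with probabilities
    ``tier_mix``; unmapped cases are split between weak hits and
    pseudogene-flagged subjects.
    """
    if abs(sum(tier_mix) - 1.0) > 1e-9:
        raise SimulationError("tier_mix must sum to 1")
    rng = np.random.default_rng(seed)
    subsystems = ["translocation", "protein_folding", "protein_transport", "UPR", "ERAD"]
    complexes = [f"CPX{i}" for i in range(n_complexes)]
    groups = [f"FG{i}" for i in range(n_groups)]

    components = []
    for i in range(n_components):
        components.append(
            Component(
                id=f"Gene{i:03d}",
                species=species,
                subsystems=frozenset({subsystems[i % len(subsystems)]}),
                functional_groups=frozenset({groups[i % n_groups]}) if n_groups else frozenset(),
                complexes=frozenset({complexes[i % n_complexes]}) if n_complexes else frozenset(),
                core=i % 3 == 0,
            )
        )
    cat = Catalogue(components=components, species=species, source="synthetic")

    interactions: list[Interaction] = []
    for i in range(n_components):
        for j in range(i + 1, n_components):
            if rng.random() < interaction_density:
                interactions.append(
                    Interaction(
                        f"Gene{i:03d}",
                        f"Gene{j:03d}",
                        "protein_protein",
                        provenance="synthetic",
                    )
                )

    tiers = rng.choice(3, size=n_components, p=list(tier_mix))
    rows = []
    for i, tier in enumerate(tiers):
        query = f"Gene{i:03d}"
        subject = f"tgt{i:03d}"
        pseudo = False
        if tier == 0:  # high: pident > 80
            pident = rng.uniform(81.0, 99.9)
            bitscore = rng.uniform(200.0, 900.0)
            evalue = 10.0 ** rng.uniform(-180.0, -30.0)
        elif tier == 1:  # moderate: 60 < pident <= 80, bitscore > 50, small evalue
            pident = rng.uniform(61.0, 79.9)
            bitscore = rng.uniform(55.0, 190.0)
            evalue = 10.0 ** rng.uniform(-60.0, -6.0)
        else:  # unmapped: weak hit or pseudogene subject
            pseudo = bool(rng.random() < 0.5)
            if pseudo:
                pident = rng.uniform(61.0, 95.0)
                bitscore = rng.uniform(55.0, 400.0)
                evalue = 10.0 ** rng.uniform(-60.0, -6.0)
            else:
                pident = rng.uniform(20.0, 59.0)
                bitscore = rng.uniform(10.0, 45.0)
                evalue = 10.0 ** rng.uniform(-4.0, 1.0)
        length = int(rng.integers(80, 600))
        rows.append(
            {
                "qseqid": query,
                "sseqid": subject,
                "pident": round(pident, 2),
                "length": length,
                "mismatch": int(length * (1 - pident / 100)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1,
                "qend": length,
                "sstart": 1,
                "send": length,
                "evalue": float(f"{evalue:.3g}"),
                "bitscore": round(bitscore, 1),
                "partial": int(rng.random() < 0.1),
                "pseudogene": int(pseudo),
                "true_tier": ["high", "moderate", "unmapped"][tier],
            }
        )
    hit_table = pd.DataFrame(rows)
    return cat, interactions, hit_table


def write_hit_table(hit_table: pd.DataFrame, path: str | Path) -> None:
    """Write the 14-column tabular hit file (truth column stripped)."""
    hit_table.drop(columns=["true_tier"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_fixture_set(
    out_dir: str | Path,
    spec: SyntheticSpec,
    *,
    n_components: int = 20,
    n_complexes: int = 2,
    n_groups: int = 3,
) -> dict[str, Path]:
    """Write a complete plain-text fixture set under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cat, interactions, hits = generate_toy_recon(
        n_components, n_complexes, n_groups, seed=spec.seed
    )
    counts, truth = generate_counts(spec)
    expr, _ = generate_modular_expression(spec)
    phenotype, _ = generate_phenotype(expr, {}, seed=spec.seed)

    paths = {
        "catalogue": out_dir / "catalogue.tsv",
        "interactions": out_dir / "interactions.tsv",
        "hits": out_dir / "hits.tsv",
        "counts": out_dir / "counts.tsv",
        "truth": out_dir / "truth.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
    }
    save_catalogue(cat, paths["catalogue"])
    save_interactions(interactions, paths["interactions"])
    write_hit_table(hits, paths["hits"])
    counts.to_csv(paths["counts"], sep="\t")
    truth.to_csv(paths["truth"], sep="\t")
    phenotype.to_frame().to_csv(paths["phenotypes"], sep="\t")
    return paths


def demo_spec(seed: int = 17) -> SyntheticSpec:
    """The default demo fixture: 1000 genes x 24 samples, 4 modules of 25."""
    return SyntheticSpec(
        n_genes=1000,
        n_samples=24,
        modules=[ModuleSpec(25)] * 4,
        noise_sd=0.3,
        seed=seed,
    )
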