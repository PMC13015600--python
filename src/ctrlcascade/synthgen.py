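"""Synthetic cohorts with fully recorded planted structure.

The generator emulates the data shapes of a large pediatric imaging-genetics
cohort so that every downstream stage has a recovery oracle:

* modular weighted structural connectomes (stochastic-block edge structure,
  log-normal QA-like weights),
* 67 mixed-type adversity indicators loading on 5 correlated latent
  factors, with median-split dichotomization and MCAR missingness,
* phenotypes with a planted mediation cascade X -> M -> Y, polygenic-score
  moderation of the a- and b-paths, study-site random intercepts, and a
  two-wave autoregressive + cross-lagged panel structure.

Two generator paths exist on purpose: the connectome generator feeds the
matrix-level controllability code, while the phenotype generator plants the
mediator M directly (there is no closed-form mapping from edge weights to a
target modal-controllability value), which makes mediation recovery exact.
All planted parameters are echoed in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ctrlcascade.connectome import NetworkPartition, StructuralConnectome, write_connectome

FACTOR_LABELS = ("F1", "F2", "F3", "F4", "F5")

# marginals for the demographic covariates (age in years; probabilities from
# a typical 9-11-year multisite cohort)
_AGE_MEAN, _AGE_SD = 9.47, 0.51
_SEX_P_MALE = 0.52
_RACE_LEVELS = ("Asian", "Black", "Hispanic", "White", "Other")
_RACE_P = (0.017, 0.150, 0.201, 0.530, 0.102)
_HAND_LEVELS = ("right", "left", "mixed")
_HAND_P = (0.799, 0.070, 0.131)


@dataclass
class GroundTruth:
    """Every planted parameter of a synthetic cohort."""

    loadings_matrix: np.ndarray  # items x factors
    factor_corr: np.ndarray  # factors x factors
    a_paths: dict  # (factor_label, network) -> coefficient
    b_paths: dict  # (network, outcome) -> coefficient
    c_prime: dict  # (factor_label, outcome) -> coefficient
    moderation_slopes: dict  # {"a": ..., "b": ..., "c_prime": ...}
    covariate_effects: dict  # covariate -> effect on outcomes
    site_sd: float
    ar_coeffs: dict  # {"brain": ..., "behavior": ...}
    crosslag_coeffs: dict  # {"brain_to_behavior": ..., "behavior_to_brain": ...}
    noise_sds: dict  # {"mediator", "outcome", "wave2"}
    seed: int
    item_types: list[str] = field(default_factory=list)  # per-item continuous/binary

    def __post_init__(self) -> None:
        self.loadings_matrix = np.asarray(self.loadings_matrix, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        fc = self.factor_corr
        if not np.allclose(fc, fc.T) or not np.allclose(np.diag(fc), 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(fc)[0] <= 0:
            raise ValueError("factor_corr must be positive definite")
        if any(s <= 0 for s in self.noise_sds.values()):
            raise ValueError("all noise_sds must be > 0")
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")
        for v in self.ar_coeffs.values():
            if not -1 < v < 1:
                raise ValueError("autoregressive coefficients must lie in (-1, 1)")

    @property
    def n_items(self) -> int:
        return self.loadings_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings_matrix.shape[1]

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["loadings_matrix"] = self.loadings_matrix.tolist()
        d["factor_corr"] = self.factor_corr.tolist()
        d["a_paths"] = {f"{k[0]}|{k[1]}": v for k, v in self.a_paths.items()}
        d["b_paths"] = {f"{k[0]}|{k[1]}": v for k, v in self.b_paths.items()}
        d["c_prime"] = {f"{k[0]}|{k[1]}": v for k, v in self.c_prime.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        for key in ("a_paths", "b_paths", "c_prime"):
            d[key] = {tuple(k.split("|")): v for k, v in d[key].items()}
        return cls(**d)


def default_ground_truth(
    n_items: int = 67,
    n_factors: int = 5,
    seed: int = 0,
    loading_range: tuple[float, float] = (0.5, 0.8),
    factor_corr_offdiag: float = 0.2,
    a: float = 0.3,
    b: float = 0.3,
    c_prime: float = 0.2,
    a_moderation: float = 0.1,
    site_sd: float = 0.3,
) -> GroundTruth:
    """Default planted structure: simple-structure loadings (one dominant
    loading per item, drawn uniformly from ``loading_range``), mildly
    correlated factors, and a single F4 -> MF-controllability -> crystallized
    mediation chain with PRS moderation on the a-path."""
    rng = np.random.default_rng(seed)
    loadings = np.zeros((n_items, n_factors))
    for i in range(n_items):
        loadings[i, i % n_factors] = rng.uniform(*loading_range)
    fc = np.full((n_factors, n_factors), factor_corr_offdiag)
    np.fill_diagonal(fc, 1.0)
    item_types = ["continuous"] * n_items
    return GroundTruth(
        loadings_matrix=loadings,
        factor_corr=fc,
        a_paths={("F4", "MF"): a},
        b_paths={("MF", "crystallized"): b},
        c_prime={("F4", "crystallized"): c_prime},
        moderation_slopes={"a": a_moderation, "b": 0.0, "c_prime": 0.0},
        covariate_effects={"age": 0.05, "sex_male": 0.1},
        site_sd=site_sd,
        ar_coeffs={"brain": 0.5, "behavior": 0.6},
        crosslag_coeffs={"brain_to_behavior": 0.3, "behavior_to_brain": 0.0},
        noise_sds={"mediator": 1.0, "outcome": 1.0, "wave2": 1.0},
        seed=seed,
        item_types=item_types,
    )


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------

def simulate_connectomes(
    n_subjects: int,
    n_nodes: int,
    partition: NetworkPartition,
    density: float = 0.3,
    weight_scale: float = 0.02,
    seed: int = 0,
    within_boost: float = 1.5,
) -> list[StructuralConnectome]:
    """Modular weighted connectomes with log-normal positive weights.

    Within-network node pairs get edge probability ``min(1, within_boost *
    density)``; the between-network probability is set so the expected
    overall density equals ``density``. Edge weights are log-normal with
    median ``weight_scale`` (QA-like scale). ``density=1`` yields the
    complete graph.
    """
    if n_nodes <= 1:
        raise ValueError("n_nodes must be > 1")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if partition.n_nodes != n_nodes:
        raise ValueError("partition size must match n_nodes")
    rng = np.random.default_rng(seed)
    labels = partition.labels
    iu, ju = np.triu_indices(n_nodes, k=1)
    same = labels[iu] == labels[ju]
    n_within = int(same.sum())
    n_between = len(iu) - n_within
    p_in = min(1.0, within_boost * density)
    if n_between > 0:
        p_out = (density * len(iu) - p_in * n_within) / n_between
        p_out = float(np.clip(p_out, 0.05 * density, 1.0))
    else:
        p_out = 0.0
    probs = np.where(same, p_in, p_out)
    out = []
    for s in range(n_subjects):
        present = rng.random(len(iu)) < probs
        weights = np.exp(rng.normal(np.log(weight_scale), 0.5, size=len(iu)))
        vals = np.where(present, weights, 0.0)
        w = np.zeros((n_nodes, n_nodes))
        w[iu, ju] = vals
        w[ju, iu] = vals
        out.append(StructuralConnectome(f"sub-{s + 1:04d}", w))
    return out


# ---------------------------------------------------------------------------
# Adversity indicators
# ---------------------------------------------------------------------------

def simulate_ela_items(
    n_subjects: int,
    truth: GroundTruth,
    missing_rate: float = 0.0,
    binarize_fraction: float = 0.0,
    noise: str = "communality",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indicator matrix from the planted measurement model.

    Items are ``Lambda f + e`` with latent factors drawn from the planted
    factor correlation. ``noise="communality"`` gives unit total variance
    (unique sd ``sqrt(1 - communality)``); ``noise="unit"`` uses unit-sd
    unique noise. A fraction of items is dichotomized by median split, and
    missingness is completely at random. Returns ``(items, latent_factors)``
    with missing cells as NaN; the latent scores are the recovery oracle.
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    if not 0 <= binarize_fraction <= 1:
        raise ValueError("binarize_fraction must lie in [0, 1]")
    lam, phi = truth.loadings_matrix, truth.factor_corr
    primary = np.abs(lam).max(axis=0)
    if (primary < 0.45).any():
        raise ValueError("each factor needs at least one item with |loading| >= 0.45")
    rng = np.random.default_rng(seed)
    f = rng.multivariate_normal(np.zeros(truth.n_factors), phi, size=n_subjects)
    communality = np.einsum("ij,jk,ik->i", lam, phi, lam)
    if noise == "communality":
        unique_sd = np.sqrt(np.clip(1.0 - communality, 0.05, None))
    elif noise == "unit":
        unique_sd = np.ones(truth.n_items)
    else:
        raise ValueError("noise must be 'communality' or 'unit'")
    e = rng.normal(0.0, 1.0, size=(n_subjects, truth.n_items)) * unique_sd
    x = f @ lam.T + e
    n_binary = int(round(binarize_fraction * truth.n_items))
    bin_idx = rng.choice(truth.n_items, size=n_binary, replace=False) if n_binary else []
    for j in bin_idx:
        x[:, j] = (x[:, j] > np.median(x[:, j])).astype(float)
    truth.item_types = [
        "binary" if j in set(np.atleast_1d(bin_idx).tolist()) else "continuous"
        for j in range(truth.n_items)
    ]
    if missing_rate > 0:
        mask = rng.random(x.shape) < missing_rate
        x = np.where(mask, np.nan, x)
    subjects = [f"sub-{i + 1:04d}" for i in range(n_subjects)]
    items = pd.DataFrame(
        x, index=subjects, columns=[f"item{j + 1:02d}" for j in range(truth.n_items)]
    )
    factors = pd.DataFrame(f, index=subjects, columns=list(FACTOR_LABELS[: truth.n_factors]))
    return items, factors


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    n_subjects: int,
    truth: GroundTruth,
    controllability: pd.DataFrame | None = None,
    factors: pd.DataFrame | None = None,
    n_sites: int = 22,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype table with the planted mediation and panel structure.

    In direct-mediator mode (``controllability=None``) the mediator columns
    are generated as ``M = sum_f a_f F_f + a_mod * F_f * PRS + site + noise``.
    If a controllability table is supplied, its network columns are used as
    the mediators instead (subject index must match). Wave-1 outcomes follow
    the planted c'/b paths with b-path moderation, covariate effects, and a
    site random intercept; wave-2 columns follow the planted autoregressive
    and cross-lagged coefficients.
    """
    rng = np.random.default_rng(seed)
    subjects = [f"sub-{i + 1:04d}" for i in range(n_subjects)]
    if factors is None:
        f = rng.multivariate_normal(
            np.zeros(truth.n_factors), truth.factor_corr, size=n_subjects
        )
        factors = pd.DataFrame(f, index=subjects, columns=list(FACTOR_LABELS[: truth.n_factors]))
    elif len(factors) != n_subjects:
        raise ValueError("factors table does not match n_subjects")

    pheno = pd.DataFrame(index=factors.index)
    pheno["site"] = rng.integers(1, n_sites + 1, size=n_subjects)
    pheno["age"] = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n_subjects), 9.0, 11.0)
    pheno["sex"] = np.where(rng.random(n_subjects) < _SEX_P_MALE, "M", "F")
    pheno["race"] = rng.choice(_RACE_LEVELS, p=_RACE_P, size=n_subjects)
    pheno["handedness"] = rng.choice(_HAND_LEVELS, p=_HAND_P, size=n_subjects)
    pheno["pubertal"] = rng.normal(0.0, 0.97, n_subjects)
    for j in range(5):
        pheno[f"pc{j + 1}"] = rng.normal(0.0, 1.0, n_subjects)
    prs = rng.normal(0.0, 1.0, n_subjects)
    pheno["prs"] = prs

    networks = sorted({net for (_, net) in truth.a_paths} | {net for (net, _) in truth.b_paths})
    site_codes = pheno["site"].to_numpy()
    a_mod = truth.moderation_slopes.get("a", 0.0)
    b_mod = truth.moderation_slopes.get("b", 0.0)

    mediators: dict[str, np.ndarray] = {}
    for net in networks:
        if controllability is not None:
            if len(controllability) != n_subjects:
                raise ValueError("controllability table does not match the subject set")
            mediators[net] = controllability[net].to_numpy(dtype=float)
        else:
            m = np.zeros(n_subjects)
            for (fac, net2), coef in truth.a_paths.items():
                if net2 != net:
                    continue
                fvals = factors[fac].to_numpy()
                m += coef * fvals + a_mod * fvals * prs
            m += _site_effects(rng, site_codes, truth.site_sd)
            m += rng.normal(0.0, truth.noise_sds["mediator"], n_subjects)
            mediators[net] = m
        pheno[f"ctrl_{net}"] = mediators[net]

    outcomes = sorted({o for (_, o) in truth.b_paths} | {o for (_, o) in truth.c_prime})
    age_c = pheno["age"].to_numpy() - _AGE_MEAN
    sex_male = (pheno["sex"] == "M").astype(float).to_numpy()
    for out in outcomes:
        y = np.zeros(n_subjects)
        for (fac, out2), coef in truth.c_prime.items():
            if out2 == out:
                y += coef * factors[fac].to_numpy()
        for (net, out2), coef in truth.b_paths.items():
            if out2 == out:
                y += coef * mediators[net] + b_mod * mediators[net] * prs
        y += truth.covariate_effects.get("age", 0.0) * age_c
        y += truth.covariate_effects.get("sex_male", 0.0) * sex_male
        y += _site_effects(rng, site_codes, truth.site_sd)
        y += rng.normal(0.0, truth.noise_sds["outcome"], n_subjects)
        pheno[f"{out}_t1"] = y

    # two-wave panel structure on the first mediator/outcome pair
    if networks and outcomes:
        brain1 = mediators[networks[0]]
        behav1 = pheno[f"{outcomes[0]}_t1"].to_numpy()
        sd2 = truth.noise_sds["wave2"]
        brain2 = (
            truth.ar_coeffs["brain"] * brain1
            + truth.crosslag_coeffs["behavior_to_brain"] * behav1
            + rng.normal(0.0, sd2, n_subjects)
        )
        behav2 = (
            truth.ar_coeffs["behavior"] * behav1
            + truth.crosslag_coeffs["brain_to_behavior"] * brain1
            + rng.normal(0.0, sd2, n_subjects)
        )
        pheno[f"ctrl_{networks[0]}_t2"] = brain2
        pheno[f"{outcomes[0]}_t2"] = behav2

    for fac in factors.columns:
        pheno[fac] = factors[fac]
    return pheno


def _site_effects(rng: np.random.Generator, site_codes: np.ndarray, site_sd: float) -> np.ndarray:
    sites = np.unique(site_codes)
    intercepts = rng.normal(0.0, site_sd, len(sites)) if site_sd > 0 else np.zeros(len(sites))
    lut = dict(zip(sites, intercepts))
    return np.array([lut[s] for s in site_codes])


# ---------------------------------------------------------------------------
# Cohort orchestration and I/O
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    connectomes: list[StructuralConnectome]
    items: pd.DataFrame
    latent_factors: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: GroundTruth
    partition: NetworkPartition | None = None

    def __post_init__(self) -> None:
        if not self.items.index.equals(self.phenotypes.index):
            raise ValueError("items and phenotypes must cover the same subjects")
        if self.connectomes and len(self.connectomes) != len(self.items):
            raise ValueError("one connectome per subject required")


def simulate_cohort(
    n_subjects: int,
    truth: GroundTruth | None = None,
    n_nodes: int = 50,
    partition: NetworkPartition | None = None,
    density: float = 0.3,
    missing_rate: float = 0.05,
    binarize_fraction: float = 0.4,
    n_sites: int = 22,
    seed: int = 0,
    with_connectomes: bool = True,
) -> SyntheticCohort:
    """Generate a complete cohort; sub-stage seeds are spawned from ``seed``."""
    if truth is None:
        truth = default_ground_truth(seed=seed)
    s_conn, s_items, s_pheno = (
        int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(3)
    )
    if partition is None and with_connectomes:
        base, rem = divmod(n_nodes, 10)
        from ctrlcascade.connectome import CANONICAL_NETWORKS

        sizes = {
            lab: base + (1 if i < rem else 0) for i, lab in enumerate(CANONICAL_NETWORKS)
        }
        partition = NetworkPartition.contiguous({k: v for k, v in sizes.items() if v > 0})
    connectomes = (
        simulate_connectomes(n_subjects, n_nodes, partition, density=density, seed=s_conn)
        if with_connectomes
        else []
    )
    items, factors = simulate_ela_items(
        n_subjects, truth, missing_rate=missing_rate,
        binarize_fraction=binarize_fraction, seed=s_items,
    )
    pheno = simulate_phenotypes(
        n_subjects, truth, factors=factors, n_sites=n_sites, seed=s_pheno
    )
    return SyntheticCohort(connectomes, items, factors, pheno, truth, partition)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort to disk: one dense CSV matrix per connectome plus a
    manifest, items/phenotypes as CSV, and the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conn_dir = outdir / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    manifest = []
    for c in cohort.connectomes:
        path = conn_dir / f"{c.subject_id}.csv"
        write_connectome(c, path)
        manifest.append({"subject_id": c.subject_id, "file": path.name, "n_nodes": c.n_nodes})
    pd.DataFrame(manifest).to_csv(conn_dir / "manifest.csv", index=False)
    if cohort.partition is not None:
        cohort.partition.to_csv(outdir / "partition.csv")
    cohort.items.to_csv(outdir / "items.csv", index_label="subject_id")
    cohort.latent_factors.to_csv(outdir / "latent_factors.csv", index_label="subject_id")
    cohort.phenotypes.to_csv(outdir / "phenotypes.csv", index_label="subject_id")
    cohort.truth.to_json(outdir / "truth.json")
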