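"""Synthetic pedigreed ordinal datasets with known truth.

Generates the study conditions used throughout the test suite: a pedigree
with discrete generations and random mating, breeding values ``u ~ N(0, A
sigma_u^2)`` simulated by Mendelian sampling down the pedigree, liabilities
``l = X beta + Z u + e`` discretised at fixed thresholds into ``C`` ordered
classes, and optional miscoding of the recorded class by a generative
misclassification matrix (rows = true class, row sums = 1).

Two named designs are provided: a large one (``d1``: pedigree of 10,000,
~9,000 phenotyped, systematic effects with 20/10/5 levels) and a small one
(``d2``: pedigree of 1,563, ~1,400 phenotyped, 5/5/5 levels), both with
``sigma_u2 = 0.1``, ``sigma_e2 = 1`` and thresholds (0, 1), giving a
liability-scale heritability of 0.1/1.1 ~ 0.091.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, inbreeding_coefficients, _mendelian_d

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "EcpError",
    "d1_config",
    "d2_config",
    "scale_config",
    "liability_sd",
    "calibrated_intercept",
    "symmetric_misclassification",
    "asymmetric_misclassification",
    "simulate_pedigree",
    "draw_systematic_effects",
    "simulate_breeding_values",
    "simulate_liabilities",
    "apply_misclassification",
    "check_ecp",
    "simulate_dataset",
]


class EcpError(RuntimeError):
    """Extreme-case problem persisted beyond the retry cap."""


@dataclass(frozen=True)
class EffectSpec:
    """One systematic effect: level count and the normal its levels are drawn from."""

    n_levels: int
    mean: float
    spread: float  # variance or SD depending on SimulationConfig.effect_param


def symmetric_misclassification(rate: float = 0.025, n_categories: int = 3) -> np.ndarray:
    """Generative P with equal miscoding rate in every direction (rows sum to 1)."""
    C = n_categories
    P = np.full((C, C), rate)
    np.fill_diagonal(P, 1.0 - rate * (C - 1))
    return P


def asymmetric_misclassification() -> np.ndarray:
    """The non-symmetric 3-class scenario: directional rates
    (pi12, pi21, pi23, pi32, pi13, pi31) = (1, 3, 1.5, 1, 0.1, 0.1)%."""
    P = np.array(
        [
            [0.0, 0.010, 0.001],
            [0.030, 0.0, 0.015],
            [0.001, 0.010, 0.0],
        ]
    )
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one replicate of the simulation design."""

    n_pedigree: int
    n_phenotyped: tuple[int, int]  # inclusive range, drawn uniformly per replicate
    effect_specs: tuple[EffectSpec, ...]
    sigma_u2: float = 0.1
    sigma_e2: float = 1.0
    thresholds: tuple[float, float] = (0.0, 1.0)
    n_categories: int = 3
    misclass_matrix: np.ndarray | None = None  # None -> identity (no miscoding)
    effect_param: str = "variance"  # Table-style second parameter: "variance" | "sd"
    intercept: float = 0.0  # added to every liability; see calibrated_intercept
    founder_fraction: float = 0.10
    max_ecp_retries: int = 100

    def __post_init__(self):
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variances must be positive")
        t = self.thresholds
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.effect_param not in ("variance", "sd"):
            raise ValueError("effect_param must be 'variance' or 'sd'")
        if self.misclass_matrix is not None:
            P = np.asarray(self.misclass_matrix, dtype=float)
            if P.shape != (self.n_categories,) * 2:
                raise ValueError("misclass_matrix must be C x C")
            if not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("misclass_matrix rows must sum to 1")
            object.__setattr__(self, "misclass_matrix", P)


def liability_sd(config: SimulationConfig) -> float:
    """Marginal SD of a random record's liability under the design."""
    v = sum(
        spec.spread if config.effect_param == "variance" else spec.spread**2
        for spec in config.effect_specs
    )
    return float(np.sqrt(v + config.sigma_u2 + config.sigma_e2))


def calibrated_intercept(config: SimulationConfig, class0_rate: float) -> float:
    """Intercept making the marginal class-0 probability equal ``class0_rate``.

    A record's liability is marginally normal (the level values, breeding
    value and residual are all normal draws), so the class-0 probability is
    ``Phi((t_0 - m) / sd)``; solving for the mean ``m`` gives the intercept
    on top of the effect means.  The named designs use this to reproduce the
    class frequencies of the study they emulate — the stated effect
    distributions alone put the bulk of the mass in the bottom class, which
    is not the regime those studies describe.
    """
    from scipy.stats import norm

    mean_effects = sum(spec.mean for spec in config.effect_specs)
    m = config.thresholds[0] - liability_sd(config) * norm.ppf(class0_rate)
    return float(m - mean_effects)


def d1_config(misclass: str | np.ndarray | None = None, **overrides) -> SimulationConfig:
    """Large design: pedigree 10,000; 8,939-9,042 phenotyped; effects 20/10/5
    levels; intercept calibrated to a 0.39 bottom-class rate."""
    return _named_config(
        n_pedigree=10_000,
        n_phenotyped=(8_939, 9_042),
        levels=(20, 10, 5),
        misclass=misclass,
        class0_rate=0.39,
        **overrides,
    )


def d2_config(misclass: str | np.ndarray | None = None, **overrides) -> SimulationConfig:
    """Small design: pedigree 1,563; 1,393-1,425 phenotyped; effects 5/5/5
    levels; intercept calibrated to a 0.36 bottom-class rate."""
    return _named_config(
        n_pedigree=1_563,
        n_phenotyped=(1_393, 1_425),
        levels=(5, 5, 5),
        misclass=misclass,
        class0_rate=0.36,
        **overrides,
    )


_EFFECT_NORMALS = ((-0.7, 0.05), (-0.1, 0.5), (0.1, 0.2))


def _named_config(n_pedigree, n_phenotyped, levels, misclass, class0_rate, **overrides):
    if isinstance(misclass, str):
        misclass = {
            "symmetric": symmetric_misclassification(),
            "asymmetric": asymmetric_misclassification(),
            "none": None,
        }[misclass]
    specs = tuple(
        EffectSpec(nl, mu, sp) for nl, (mu, sp) in zip(levels, _EFFECT_NORMALS)
    )
    cfg = SimulationConfig(
        n_pedigree=n_pedigree,
        n_phenotyped=n_phenotyped,
        effect_specs=specs,
        misclass_matrix=misclass,
        **overrides,
    )
    if "intercept" not in overrides:
        cfg = replace(cfg, intercept=calibrated_intercept(cfg, class0_rate))
    return cfg


def scale_config(config: SimulationConfig, factor: float) -> SimulationConfig:
    """Shrink a design's pedigree / phenotype counts by ``factor`` (levels kept)."""
    lo, hi = config.n_phenotyped
    return replace(
        config,
        n_pedigree=max(10, round(config.n_pedigree * factor)),
        n_phenotyped=(max(5, round(lo * factor)), max(5, round(hi * factor))),
    )


@dataclass
class SimulatedDataset:
    """One simulated replicate with full truth retained."""

    pedigree: Pedigree
    records: pd.DataFrame  # animal (internal code), level_<f>, liability, true_class, observed_class, miscoded
    true_u: np.ndarray  # per pedigree animal, internal order
    true_beta: tuple[np.ndarray, ...]  # per effect, per level
    config: SimulationConfig
    seed: int
    n_attempts: int = 1

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def incidences(self) -> np.ndarray:
        """Observed relative class frequencies."""
        C = self.config.n_categories
        counts = np.bincount(self.records["observed_class"], minlength=C)
        return counts / counts.sum()

    @property
    def miscoding_rate(self) -> float:
        return float(self.records["miscoded"].mean())

    def phenotypes_frame(self) -> pd.DataFrame:
        """What a field dataset would contain: IDs, effect levels, observed class."""
        cols = {"animal": self.pedigree.original_ids[self.records["animal"] - 1]}
        for f in range(len(self.true_beta)):
            cols[f"effect{f + 1}"] = self.records[f"level_{f}"].to_numpy() + 1
        cols["response"] = self.records["observed_class"].to_numpy()
        return pd.DataFrame(cols)

    def truth_frame(self) -> pd.DataFrame:
        out = self.records.copy()
        out.insert(0, "animal_id", self.pedigree.original_ids[out["animal"] - 1])
        out["true_u"] = self.true_u[out["animal"] - 1]
        return out


def simulate_pedigree(
    n_animals: int, n_founders: int, seed: int | np.random.Generator
) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders (unknown parents) come first; subsequent generations of (up to)
    ``n_founders`` animals draw a sire among the previous generation's males
    and a dam among its females.
    """
    if n_founders > n_animals:
        raise ValueError("n_founders cannot exceed n_animals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sire = np.zeros(n_animals, dtype=np.int64)
    dam = np.zeros(n_animals, dtype=np.int64)
    sex = rng.integers(0, 2, size=n_animals)  # 0 = male, 1 = female
    gen_start, gen_end = 0, n_founders
    while gen_end < n_animals:
        # guarantee both sexes in the parent generation
        gsex = sex[gen_start:gen_end]
        if (gsex == 0).sum() == 0:
            sex[gen_start] = 0
        if (gsex == 1).sum() == 0:
            sex[gen_end - 1] = 1
        prev = np.arange(gen_start, gen_end)
        males = prev[sex[prev] == 0] + 1
        females = prev[sex[prev] == 1] + 1
        nxt_end = min(gen_end + n_founders, n_animals)
        size = nxt_end - gen_end
        sire[gen_end:nxt_end] = rng.choice(males, size=size)
        dam[gen_end:nxt_end] = rng.choice(females, size=size)
        gen_start, gen_end = gen_end, nxt_end
    return Pedigree(sire=sire, dam=dam)


def draw_systematic_effects(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[np.ndarray, ...]:
    """Per-level effect values, independently normal within each effect."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for spec in config.effect_specs:
        sd = np.sqrt(spec.spread) if config.effect_param == "variance" else spec.spread
        out.append(rng.normal(spec.mean, sd, size=spec.n_levels))
    return tuple(out)


def simulate_breeding_values(
    ped: Pedigree, sigma_u2: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Breeding values with covariance ``A sigma_u2`` via Mendelian sampling.

    ``u_i = 0.5 (u_s + u_d) + m_i`` with ``var(m_i) = sigma_u2 * d_i``, where
    ``d_i`` is the inbreeding-corrected Mendelian sampling variance ratio;
    unknown parents contribute 0 with compensating variance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = ped.n_animals
    if sigma_u2 == 0:
        return np.zeros(q)
    F = inbreeding_coefficients(ped)
    s = ped.sire - 1
    d = ped.dam - 1
    z = rng.standard_normal(q)
    u = np.empty(q)
    for i in range(q):
        mean = 0.0
        if s[i] >= 0:
            mean += 0.5 * u[s[i]]
        if d[i] >= 0:
            mean += 0.5 * u[d[i]]
        u[i] = mean + z[i] * np.sqrt(sigma_u2 * _mendelian_d(F, s[i], d[i]))
    return u


def simulate_liabilities(
    eta: np.ndarray,
    sigma_e2: float,
    thresholds: tuple[float, ...],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Add residuals and discretise: class j iff t_{j-1} < l <= t_j.

    A liability exactly at a threshold falls in the lower class (half-open
    intervals ``(t_{j-1}, t_j]``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    liab = eta + rng.normal(0.0, np.sqrt(sigma_e2), size=len(eta))
    classes = np.searchsorted(np.asarray(thresholds), liab, side="left")
    return liab, classes.astype(np.int64)


def apply_misclassification(
    true_classes: np.ndarray,
    misclass_matrix: np.ndarray,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Record each observation as class k with probability P[true, k]."""
    P = np.asarray(misclass_matrix, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("misclass_matrix rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)[true_classes]  # n x C
    u = rng.random(len(true_classes))
    observed = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    return observed, observed != true_classes


def check_ecp(dataset: SimulatedDataset) -> bool:
    """True iff some systematic-effect level shows a single observed class.

    Such a level (an "extreme-case problem") makes its effect inestimable on
    the liability scale; the simulator regenerates replicates until absent.
    """
    y = dataset.records["observed_class"]
    for f in range(len(dataset.true_beta)):
        for _, grp in y.groupby(dataset.records[f"level_{f}"]):
            if grp.nunique() < 2:
                return True
    return False


def simulate_dataset(config: SimulationConfig, seed: int) -> SimulatedDataset:
    """Draw one full replicate; regenerates (seed offset) if an ECP occurs."""
    for attempt in range(config.max_ecp_retries):
        ds = _simulate_once(config, seed, attempt)
        if not check_ecp(ds):
            ds.n_attempts = attempt + 1
            return ds
    raise EcpError(
        f"extreme-case problem persisted after {config.max_ecp_retries} attempts"
    )


def _simulate_once(config: SimulationConfig, seed: int, attempt: int) -> SimulatedDataset:
    streams = np.random.SeedSequence([seed, attempt]).spawn(6)
    rng_ped, rng_eff, rng_u, rng_lvl, rng_res, rng_mis = map(
        np.random.default_rng, streams
    )
    n_founders = max(2, round(config.n_pedigree * config.founder_fraction))
    ped = simulate_pedigree(config.n_pedigree, n_founders, rng_ped)
    beta = draw_systematic_effects(config, rng_eff)
    u = simulate_breeding_values(ped, config.sigma_u2, rng_u)

    lo, hi = config.n_phenotyped
    n_phen = int(rng_lvl.integers(lo, hi + 1))
    non_founders = np.flatnonzero(~ped.is_founder) + 1
    pool = non_founders if len(non_founders) >= n_phen else np.arange(1, ped.n_animals + 1)
    animals = pool[-n_phen:]  # the latest pedigree members carry phenotypes

    levels = {
        f"level_{f}": rng_lvl.integers(0, spec.n_levels, size=n_phen)
        for f, spec in enumerate(config.effect_specs)
    }
    eta = config.intercept + u[animals - 1] + sum(
        beta[f][levels[f"level_{f}"]] for f in range(len(beta))
    )
    liab, true_cls = simulate_liabilities(
        eta, config.sigma_e2, config.thresholds, rng_res
    )
    if config.misclass_matrix is not None:
        observed, miscoded = apply_misclassification(
            true_cls, config.misclass_matrix, rng_mis
        )
    else:
        observed, miscoded = true_cls.copy(), np.zeros(n_phen, dtype=bool)

    records = pd.DataFrame({"animal": animals, **levels})
    records["liability"] = liab
    records["true_class"] = true_cls
    records["observed_class"] = observed
    records["miscoded"] = miscoded
    return SimulatedDataset(
        pedigree=ped,
        records=records,
        true_u=u,
        true_beta=beta,
        config=config,
        seed=seed,
    )
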