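"""Model/Results front end for the misclassification-aware threshold model.

Typical use::

    model = OrdinalMisclassModel.from_dataframe(
        phenotypes, pedigree, response="response",
        effects=["effect1", "effect2", "effect3"], animal="animal",
        misclassification=True,
    )
    res = model.fit(n_iter=20_000, seed=1)
    print(res.summary())
    res.ebv            # posterior-mean breeding values, indexed by animal ID
    res.misclass       # per-record miscoding probabilities

``misclassification=False`` gives the classical threshold animal model (the
latent true class pinned to the observation); ``pi_fixed=...`` fixes the
misclassification matrix (known-P mode) while still sampling the per-record
switching indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_a_inverse
from .threshold_model import ChainOutput, ChainSettings, PriorSpec, run_chain

__all__ = ["OrdinalMisclassModel", "OrdinalMisclassResults"]


class OrdinalMisclassModel:
    """Bayesian threshold animal model for an ordinal trait, with optional
    misclassification layer.

    Parameters
    ----------
    response : array of int
        Observed ordinal classes, coded 0..C-1.
    effects : 2-d array of int
        Per-record level codes of the systematic effects, one column per
        effect (arbitrary codes; re-indexed internally).
    animal_ids : array
        Animal identifier per record; every ID must occur in ``pedigree``.
    pedigree : Pedigree
        Grounds the additive relationship structure A.
    """

    def __init__(
        self,
        response,
        effects,
        animal_ids,
        pedigree: Pedigree,
        *,
        n_categories: int | None = None,
        prior: PriorSpec | None = None,
        misclassification: bool = False,
        pi_fixed=None,
        effect_names=None,
    ):
        y = np.asarray(response, dtype=np.int64)
        eff = np.atleast_2d(np.asarray(effects, dtype=np.int64))
        if eff.shape[0] != len(y):
            eff = eff.T
        if eff.shape[0] != len(y):
            raise ValueError("effects and response lengths differ")
        C = int(n_categories) if n_categories else int(y.max()) + 1
        if y.min() < 0 or y.max() >= C:
            raise ValueError(f"response classes must lie in 0..{C - 1}")
        code = pedigree.id_to_code()
        try:
            animal = np.array([code[a] - 1 for a in np.asarray(animal_ids)],
                              dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"animal {exc.args[0]!r} not in pedigree") from None

        # re-index each effect's levels to a dense global numbering
        n_eff = eff.shape[1]
        self.effect_names = list(effect_names) if effect_names is not None else [
            f"effect{f + 1}" for f in range(n_eff)
        ]
        eff_idx = np.empty_like(eff)
        self.level_labels: list[np.ndarray] = []
        offset = 0
        for f in range(n_eff):
            codes, uniques = pd.factorize(eff[:, f], sort=True)
            eff_idx[:, f] = codes + offset
            self.level_labels.append(np.asarray(uniques))
            offset += len(uniques)
        self.n_levels_total = offset

        self.endog = y
        self.eff_idx = eff_idx
        self.animal = animal
        self.animal_ids = np.asarray(animal_ids)
        self.pedigree = pedigree
        self.n_categories = C
        self.prior = prior or PriorSpec()
        self.misclassification = bool(misclassification) or pi_fixed is not None
        self.pi_fixed = None if pi_fixed is None else np.asarray(pi_fixed, float)
        self._a_inv = None

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        pedigree: Pedigree,
        *,
        response: str = "response",
        effects=("effect1", "effect2", "effect3"),
        animal: str = "animal",
        **kwargs,
    ) -> "OrdinalMisclassModel":
        """Build from a phenotype table (one row per record)."""
        effects = list(effects)
        return cls(
            data[response].to_numpy(),
            data[effects].to_numpy(),
            data[animal].to_numpy(),
            pedigree,
            effect_names=effects,
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, dataset, *, use_true_classes: bool = False, **kwargs):
        """Build from a :class:`~ordmisfit.simulate.SimulatedDataset`.

        ``use_true_classes=True`` analyses the noise-free classes (the
        study-style M1/M5 analyses); otherwise the recorded ones.
        """
        rec = dataset.records
        n_eff = len(dataset.true_beta)
        col = "true_class" if use_true_classes else "observed_class"
        return cls(
            rec[col].to_numpy(),
            rec[[f"level_{f}" for f in range(n_eff)]].to_numpy(),
            dataset.pedigree.original_ids[rec["animal"].to_numpy() - 1],
            dataset.pedigree,
            n_categories=dataset.config.n_categories,
            **kwargs,
        )

    @property
    def a_inv(self):
        if self._a_inv is None:
            self._a_inv = build_a_inverse(self.pedigree)
        return self._a_inv

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def fit(
        self,
        n_iter: int = 20_000,
        burnin: int | None = None,
        thin: int = 10,
        seed: int = 0,
        settings: ChainSettings | None = None,
    ) -> "OrdinalMisclassResults":
        """Run the Gibbs sampler and return the posterior results."""
        settings = settings or ChainSettings(n_iter=n_iter, burnin=burnin, thin=thin)
        out = run_chain(
            self.endog,
            self.eff_idx,
            self.animal,
            self.n_levels_total,
            self.a_inv,
            self.prior,
            settings,
            misclass_enabled=self.misclassification,
            pi_fixed=self.pi_fixed,
            n_categories=self.n_categories,
            seed=seed,
        )
        return OrdinalMisclassResults(self, out)


@dataclass
class OrdinalMisclassResults:
    """Posterior summaries of a fitted threshold model."""

    model: OrdinalMisclassModel
    chain: ChainOutput

    # -- scalar parameters ---------------------------------------------
    @property
    def sigma_u2_samples(self) -> np.ndarray:
        return self.chain.sigma_u2_samples

    @property
    def t1_samples(self) -> np.ndarray:
        return self.chain.t1_samples

    @property
    def h2_samples(self) -> np.ndarray:
        """Liability-scale heritability draws sigma_u2 / (sigma_u2 + 1)."""
        s = self.chain.sigma_u2_samples
        return s / (s + 1.0)

    @property
    def sigma_u2(self) -> float:
        return float(self.chain.sigma_u2_samples.mean())

    @property
    def heritability(self) -> float:
        return float(self.h2_samples.mean())

    # -- vectors ---------------------------------------------------------
    @property
    def ebv(self) -> pd.Series:
        """Posterior-mean breeding value per pedigree animal (original IDs)."""
        return pd.Series(
            self.chain.u_mean,
            index=pd.Index(self.model.pedigree.original_ids, name="animal"),
            name="ebv",
        )

    @property
    def beta(self) -> pd.Series:
        labels = [
            f"{name}[{lvl}]"
            for name, lvls in zip(self.model.effect_names, self.model.level_labels)
            for lvl in lvls
        ]
        return pd.Series(self.chain.beta_mean, index=labels, name="beta")

    @property
    def pi(self) -> pd.DataFrame:
        """Posterior mean misclassification matrix P(observed k | true j)."""
        C = self.model.n_categories
        return pd.DataFrame(
            self.chain.pi_mean,
            index=pd.Index(range(C), name="true"),
            columns=pd.Index(range(C), name="observed"),
        )

    @property
    def switch_counts(self) -> pd.DataFrame:
        """Posterior-mean switch-count matrix gamma."""
        C = self.model.n_categories
        return pd.DataFrame(
            self.chain.gamma_mean,
            index=pd.Index(range(C), name="true"),
            columns=pd.Index(range(C), name="observed"),
        )

    @property
    def misclass(self) -> pd.DataFrame:
        """Per-record posterior miscoding probability and modal true class."""
        return pd.DataFrame(
            {
                "animal": self.model.animal_ids,
                "observed_class": self.model.endog,
                "p_miscoded": self.chain.misclass_prob,
                "modal_true_class": self.chain.r_tally.argmax(axis=1),
            }
        )

    @property
    def n_retained(self) -> int:
        return self.chain.n_retained

    # -- summaries -------------------------------------------------------
    def hpd(self, param: str = "sigma_u2", mass: float = 0.95):
        from .posterior import hpd_interval

        draws = getattr(self, f"{param}_samples")
        return hpd_interval(draws, mass)

    def summary(self) -> pd.DataFrame:
        from .posterior import hpd_interval

        rows = {}
        for name in ("sigma_u2", "t1", "h2"):
            draws = getattr(self, f"{name}_samples")
            lo, hi = hpd_interval(draws, 0.95)
            rows[name] = {
                "mean": draws.mean(),
                "sd": draws.std(ddof=1),
                "hpd95_lo": lo,
                "hpd95_hi": hi,
            }
        df = pd.DataFrame(rows).T
        df.index.name = "parameter"
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        mode = (
            "known-P misclassification"
            if self.model.pi_fixed is not None
            else "estimated misclassification"
            if self.model.misclassification
            else "classical"
        )
        return (
            f"<OrdinalMisclassResults: {mode} threshold model, "
            f"n={self.model.nobs}, q={self.model.pedigree.n_animals}, "
            f"sigma_u2={self.sigma_u2:.4f}>"
        )
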