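"""RR-BLUP genomic prediction: REML variance components, marker-effect BLUPs,
GEBVs, closed-form ridge-posterior sampling and training-panel management.

The model is the standard single-trait ridge-regression mixed model

    y = 1 beta + Z u + eps,   u ~ N(0, sigma_u^2 I_k),  eps ~ N(0, sigma_e^2 I_n)

with Z the n x k marker matrix coded -1/0/1.  The two variance components are
estimated by profile REML over the ratio lambda = sigma_u^2 / sigma_e^2 using
a spectral decomposition of the marker kernel ZZ', after which the BLUPs have
the closed form u_hat = sigma_u^2 Z' V^{-1} (y - 1 beta_hat).

``RidgeBLUP`` is the model object (built from data); ``fit()`` returns a
``RidgeBLUPResults`` carrying the estimates, GEBV scoring, posterior sampling
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RidgeBLUP", "RidgeBLUPResults", "TrainingPanel", "tails_update"]


class RidgeBLUP:
    """Ridge-regression BLUP model of phenotypes on marker genotypes.

    Parameters
    ----------
    y : ndarray (n,)
        Phenotypes.  Must be finite with positive variance.
    Z : ndarray (n, k)
        Marker genotypes coded -1/0/1 (any real coding is accepted).
    """

    def __init__(self, y: np.ndarray, Z: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        Z = np.asarray(Z, dtype=float)
        if y.ndim != 1 or Z.ndim != 2 or Z.shape[0] != y.size:
            raise ValueError("y must be (n,) and Z (n, k) with matching n")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(Z)):
            raise ValueError("phenotypes and genotypes must be finite")
        if y.size < 2:
            raise ValueError("need at least two training records")
        if np.var(y) == 0:
            raise ValueError("phenotypic variance is zero: degenerate fit")
        self.y = y
        self.Z = Z
        self.nobs, self.k = Z.shape

    @classmethod
    def from_panel(cls, panel: "TrainingPanel") -> "RidgeBLUP":
        return cls(panel.y, panel.Z)

    # -- profile REML ------------------------------------------------------

    def _profile(self, log_lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
        """Profile restricted log-likelihood pieces at ratio 10**log_lam."""
        lam = 10.0**log_lam
        w = lam * d + 1.0
        xtw = xt / w
        xwx = float(xtw @ xt)
        beta = float(xtw @ yt) / xwx
        r = yt - beta * xt
        q = float((r * r / w).sum())
        n = yt.size
        sigma_e2 = q / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(sigma_e2) + np.log(w).sum() + np.log(xwx) + (n - 1)
        )
        return ll, beta, sigma_e2, w, r

    def fit(self, log_lambda_bounds: tuple[float, float] = (-8.0, 8.0), grid: int = 33):
        """Estimate (sigma_u^2, sigma_e^2) by profile REML, then BLUP u_hat.

        A coarse grid over log10(lambda) brackets the optimum, which is then
        refined with bounded scalar minimization.
        """
        y, Z = self.y, self.Z
        n = self.nobs
        K = Z @ Z.T
        if not np.any(K):
            # no marker information: mean-only model
            return RidgeBLUPResults(
                model=self,
                beta=float(y.mean()),
                u=np.zeros(self.k),
                sigma_u2=0.0,
                sigma_e2=float(np.var(y, ddof=1)),
                reml_loglike=float("nan"),
            )
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        yt = U.T @ y
        xt = U.T @ np.ones(n)

        lo, hi = log_lambda_bounds
        xs = np.linspace(lo, hi, grid)
        lls = np.array([self._profile(x, d, yt, xt)[0] for x in xs])
        i = int(np.argmax(lls))
        a = xs[max(i - 1, 0)]
        b = xs[min(i + 1, grid - 1)]
        res = minimize_scalar(
            lambda x: -self._profile(x, d, yt, xt)[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        ll, beta, sigma_e2, w, r = self._profile(log_lam, d, yt, xt)
        lam = 10.0**log_lam
        # u_hat = sigma_u^2 Z' V^{-1} (y - 1 beta) = lam * Z' U (r / w)
        u = lam * (Z.T @ (U @ (r / w)))
        return RidgeBLUPResults(
            model=self,
            beta=beta,
            u=u,
            sigma_u2=lam * sigma_e2,
            sigma_e2=sigma_e2,
            reml_loglike=ll,
        )


@dataclass
class RidgeBLUPResults:
    """Fitted RR-BLUP model: estimates, scoring and posterior sampling."""

    model: RidgeBLUP
    beta: float
    u: np.ndarray
    sigma_u2: float
    sigma_e2: float
    reml_loglike: float
    _chol: np.ndarray | None = field(default=None, repr=False)

    def gebv(self, Z: np.ndarray) -> np.ndarray:
        """Genomic estimated breeding values g_hat = Z u_hat.

        The fixed mean is excluded: only rankings and contrasts matter for
        selection.
        """
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[None]
        if Z.shape[1] != self.u.size:
            raise ValueError(
                f"genotype matrix has {Z.shape[1]} markers, model has {self.u.size}"
            )
        return Z @ self.u

    def sample_marker_effects(
        self, n_samples: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw from the Gaussian conditional distribution of u given y.

        Under the fitted ridge model u | y ~ N(u_hat, C) with
        C = (Z'Z / sigma_e^2 + I / sigma_u^2)^{-1}.  These draws play the
        role MCMC samples of marker effects play in Bayesian ridge
        implementations; the sample mean converges to u_hat.
        """
        if self.sigma_u2 == 0.0:
            return np.zeros((n_samples, self.u.size))
        if self._chol is None:
            Z = self.model.Z
            prec = Z.T @ Z / self.sigma_e2 + np.eye(self.u.size) / self.sigma_u2
            self._chol = np.linalg.cholesky(prec)
        # x = L^{-T} z  has covariance (L L')^{-1} = C
        z = rng.standard_normal((self.u.size, n_samples))
        x = np.linalg.solve(self._chol.T, z)
        return self.u[None, :] + x.T

    def summary(self) -> str:
        lines = [
            "RR-BLUP (profile REML)",
            "-" * 46,
            f"{'n obs':<28}{self.model.nobs:>18}",
            f"{'n markers':<28}{self.model.k:>18}",
            f"{'beta (fixed mean)':<28}{self.beta:>18.6g}",
            f"{'sigma_u^2':<28}{self.sigma_u2:>18.6g}",
            f"{'sigma_e^2':<28}{self.sigma_e2:>18.6g}",
            f"{'REML log-likelihood':<28}{self.reml_loglike:>18.6g}",
            f"{'|u| max':<28}{np.abs(self.u).max():>18.6g}",
        ]
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"marker": np.arange(1, self.u.size + 1), "u_hat": self.u}
        )

    def dump(self, out_dir, cycle: int | None = None) -> None:
        """Write the marker-effect table plus a small JSON header."""
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "marker_effects.tsv", sep="\t", index=False)
        header = {
            "beta": self.beta,
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "n_obs": self.model.nobs,
            "n_markers": self.model.k,
            "cycle": cycle,
        }
        (out / "model.json").write_text(json.dumps(header, indent=2) + "\n")


class TrainingPanel:
    """FIFO training panel of phenotyped individuals.

    Entries are kept in the order they were added.  ``capacity`` is fixed at
    the initial panel size the first time it is sealed; after each update the
    longest-resident entries beyond capacity are dropped.
    """

    def __init__(
        self,
        Z: np.ndarray,
        y: np.ndarray,
        ids: np.ndarray,
        cycle_added: np.ndarray | int = 0,
    ) -> None:
        self.Z = np.asarray(Z, dtype=np.float64)
        self.y = np.asarray(y, dtype=float)
        self.ids = np.asarray(ids, dtype=np.int64)
        if np.isscalar(cycle_added):
            cycle_added = np.full(self.y.size, cycle_added, dtype=np.int64)
        self.cycle_added = np.asarray(cycle_added, dtype=np.int64)
        if not (self.Z.shape[0] == self.y.size == self.ids.size == self.cycle_added.size):
            raise ValueError("panel arrays must be aligned")
        self.capacity = self.y.size

    def __len__(self) -> int:
        return int(self.y.size)

    def append(self, Z: np.ndarray, y: np.ndarray, ids: np.ndarray, cycle: int) -> None:
        self.Z = np.vstack([self.Z, np.asarray(Z, dtype=np.float64)])
        self.y = np.concatenate([self.y, np.asarray(y, dtype=float)])
        self.ids = np.concatenate([self.ids, np.asarray(ids, dtype=np.int64)])
        self.cycle_added = np.concatenate(
            [self.cycle_added, np.full(len(ids), cycle, dtype=np.int64)]
        )

    def trim(self) -> None:
        """Drop the longest-resident entries beyond capacity (FIFO order)."""
        excess = len(self) - self.capacity
        if excess > 0:
            self.Z = self.Z[excess:]
            self.y = self.y[excess:]
            self.ids = self.ids[excess:]
            self.cycle_added = self.cycle_added[excess:]


def tails_update(
    panel: TrainingPanel,
    genotypes: np.ndarray,
    gebvs: np.ndarray,
    ids: np.ndarray,
    phenotyper,
    cycle: int,
    n_add: int = 150,
) -> TrainingPanel:
    """Refresh the panel with the two tails of the GEBV distribution.

    Selects ``n_add/2`` highest- and ``n_add/2`` lowest-GEBV candidates,
    phenotypes them via ``phenotyper(candidate_index_array)``, appends them
    and drops the longest-resident entries so the panel size is conserved at
    steady state.  Boundary ties break by ascending individual id.
    """
    gebvs = np.asarray(gebvs, dtype=float)
    ids = np.asarray(ids)
    if gebvs.size < n_add:
        raise ValueError(f"need at least {n_add} candidates, got {gebvs.size}")
    half = n_add // 2
    # ascending GEBV, ties by ascending id
    order = np.lexsort((ids, gebvs))
    chosen = np.concatenate([order[:half], order[-(n_add - half):]])
    y_new = phenotyper(chosen)
    panel.append(np.asarray(genotypes)[chosen], y_new, ids[chosen], cycle)
    panel.trim()
    return panel
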