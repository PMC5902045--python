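"""Biophysical occupancy model of protein-DNA binding.

A site with mismatch energy E (natural-log units, 0 at the motif
consensus) is bound with probability

    predicted = M / (1 + exp(E - mu))

where mu is the chemical potential (a site with E = mu is half-maximally
bound) and M is a scaling factor pinned to the maximum observed
proportion bound.  Only mu is free; it is estimated from (E, observed)
pairs by gradient descent on the sum of squared residuals, the classic
fit to quantitative EMSA titrations.

The API follows the statsmodels Model/Results idiom::

    res = OccupancyModel(observed, energies).fit()
    res.mu, res.M, res.loss
    res.predict(new_energies)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OccupancyModel", "OccupancyResults", "predicted_binding", "fit_occupancy"]


def predicted_binding(E, mu: float, M: float = 1.0):
    """Logistic occupancy M / (1 + e^(E - mu)); decreasing in E, range (0, M)."""
    if not (0.0 < M <= 1.0):
        raise ValueError("M must be in (0, 1]")
    if not np.isfinite(mu):
        raise ValueError("mu must be finite")
    E = np.asarray(E, dtype=float)
    out = M / (1.0 + np.exp(E - mu))
    return float(out) if out.ndim == 0 else out


class OccupancyModel:
    """Occupancy model for proportion-bound measurements.

    Parameters
    ----------
    endog : array-like
        Observed proportions bound, each in [0, 1].
    exog : array-like
        Site mismatch energies E (natural-log units), same length.

    M is not estimated: it is fixed to ``max(endog)``, the maximum
    observed probe bound.
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.shape != self.exog.shape or self.endog.ndim != 1:
            raise ValueError("endog and exog must be equal-length 1-d arrays")
        if self.endog.size < 3:
            raise ValueError("need at least 3 (energy, proportion) pairs")
        if np.any((self.endog < 0) | (self.endog > 1)):
            raise ValueError("observed proportions must lie in [0, 1]")
        if np.ptp(self.endog) == 0:
            raise ValueError(
                "all observed proportions are equal; mu is unidentifiable"
            )
        self.M = float(self.endog.max())

    @classmethod
    def from_dataframe(cls, data, observed: str = "proportion_bound",
                       energy: str = "E") -> "OccupancyModel":
        return cls(data[observed].to_numpy(), data[energy].to_numpy())

    def _loss_grad(self, mu: float) -> tuple[float, float]:
        pred = self.M / (1.0 + np.exp(self.exog - mu))
        resid = pred - self.endog
        # d pred / d mu = pred * (1 - pred / M)
        grad = float(2.0 * np.sum(resid * pred * (1.0 - pred / self.M)))
        return float(np.sum(resid ** 2)), grad

    def fit(self, learning_rate: float = 0.05, tol: float = 1e-8,
            maxiter: int = 100_000) -> "OccupancyResults":
        """Estimate mu by gradient descent from mu0 = median(E).

        Converges when the loss improvement drops below ``tol``; raises
        if ``maxiter`` iterations pass without convergence.
        """
        mu = float(np.median(self.exog))
        loss, grad = self._loss_grad(mu)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            mu_new = mu - learning_rate * grad
            loss_new, grad_new = self._loss_grad(mu_new)
            if loss_new > loss:
                # backtrack: halve the step until the loss decreases
                lr = learning_rate
                while loss_new > loss and lr > 1e-16:
                    lr *= 0.5
                    mu_new = mu - lr * grad
                    loss_new, grad_new = self._loss_grad(mu_new)
            if abs(loss - loss_new) < tol:
                mu, loss, grad = mu_new, loss_new, grad_new
                converged = True
                break
            mu, loss, grad = mu_new, loss_new, grad_new
        if not converged:
            raise RuntimeError(
                f"gradient descent did not converge in {maxiter} iterations"
            )
        return OccupancyResults(self, mu=mu, loss=loss, niter=it)


@dataclass
class OccupancyResults:
    """Fitted occupancy model: estimates, fit diagnostics, predictions."""

    model: OccupancyModel
    mu: float
    loss: float
    niter: int

    @property
    def M(self) -> float:
        return self.model.M

    def predict(self, energies=None):
        E = self.model.exog if energies is None else energies
        return predicted_binding(E, self.mu, self.M)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.predict()

    def summary(self) -> str:
        n = self.model.endog.size
        rss = self.loss
        tss = float(np.sum((self.model.endog - self.model.endog.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        lines = [
            "Occupancy model fit (logistic in site energy)",
            "=" * 46,
            f"n sites:              {n}",
            f"mu (chemical pot.):   {self.mu:.6f}",
            f"M  (max bound, fixed):{self.M: .6f}",
            f"RSS:                  {rss:.6g}",
            f"R-squared:            {r2:.4f}",
            f"iterations:           {self.niter}",
        ]
        return "\n".join(lines)


def fit_occupancy(energies, observed, **fit_kwargs) -> OccupancyResults:
    """Convenience wrapper: build an :class:`OccupancyModel` and fit it."""
    return OccupancyModel(observed, energies).fit(**fit_kwargs)
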