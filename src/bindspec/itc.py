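"""One-site ITC binding isotherms: forward model, fitting, thermodynamics.

An isothermal titration calorimetry experiment titrates a syringe
species (here: protein) into a cell containing its partner (here: DNA)
and integrates the heat evolved per injection.  For one set of ``n``
independent and identical sites the bound-complex concentration follows
the closed-form root of the quadratic mass balance, and the fitted
(Kd, dH, n) yield the full thermodynamic profile through
dG = -R T ln Kd = dH - T dS.

Units follow the instrument convention: concentrations in mol/L,
volumes in L, heats in kcal per mol of injectant, R = 1.987e-3
kcal/(mol K).

Dilution bookkeeping uses the constant-volume displacement (perfusion)
correction: an injection of volume v displaces an equal volume of
well-mixed cell content, so after injection ``v``::

    [cell]   <- [cell]   * (1 - v/V0)
    [titrant]<- [titrant]* (1 - v/V0) + [syringe] * v/V0

and the heat of the injection is dH * V0 * (PL_i - PL_{i-1} * (1 - v/V0)),
i.e. complex carried out with the displaced volume releases no heat in
the cell.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

R_KCAL = 1.987e-3  # kcal / (mol K)


# --------------------------------------------------------------------- types

@dataclass
class Isotherm:
    """An ITC injection series.

    ``heats`` are integrated heats in kcal per mol of injectant; ``None``
    for a bare injection schedule (forward-model input).
    """

    injection_volumes: np.ndarray          # L, per injection
    cell_volume: float                     # L
    cell_conc: float                       # mol/L of the cell species (DNA)
    syringe_conc: float                    # mol/L of the titrant (protein)
    temperature: float = 293.15            # K
    heats: Optional[np.ndarray] = None     # kcal / mol injectant

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.injection_volumes.ndim != 1 or self.injection_volumes.size < 2:
            raise ValueError("need at least 2 injections")
        if (self.injection_volumes <= 0).any():
            raise ValueError("injection volumes must be positive")
        for name in ("cell_volume", "cell_conc", "syringe_conc", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats and injection_volumes must align")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size

    def concentrations(self) -> Tuple[np.ndarray, np.ndarray]:
        """Total cell-species and titrant concentrations after each
        injection, under the displacement dilution model."""
        v = self.injection_volumes
        f = 1.0 - v / self.cell_volume
        if (f <= 0).any():
            raise ValueError("injection volume exceeds the cell volume")
        M = np.empty_like(v)
        X = np.empty_like(v)
        m, x = self.cell_conc, 0.0
        for i, (vi, fi) in enumerate(zip(v, f)):
            m *= fi
            x = x * fi + self.syringe_conc * vi / self.cell_volume
            M[i], X[i] = m, x
        return M, X

    def molar_ratios(self) -> np.ndarray:
        """Titrant:cell molar ratio after each injection."""
        M, X = self.concentrations()
        return X / M

    # ----------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        ratios = self.molar_ratios()
        with open(path, "w") as fh:
            fh.write(f"# cell_volume_L\t{self.cell_volume:.10g}\n")
            fh.write(f"# cell_conc_M\t{self.cell_conc:.10g}\n")
            fh.write(f"# syringe_conc_M\t{self.syringe_conc:.10g}\n")
            fh.write(f"# temperature_K\t{self.temperature:.10g}\n")
            fh.write("injection_index\tvolume_L\tmolar_ratio\theat_kcal_per_mol_injectant\n")
            for i, v in enumerate(self.injection_volumes):
                h = "" if self.heats is None else f"{self.heats[i]:.10g}"
                fh.write(f"{i + 1}\t{v:.10g}\t{ratios[i]:.10g}\t{h}\n")

    @classmethod
    def from_tsv(cls, path) -> "Isotherm":
        meta = {}
        vols, heats = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, val = line[1:].split("\t")
                    meta[key.strip()] = float(val)
                elif line and not line.startswith("injection_index"):
                    parts = line.split("\t")
                    vols.append(float(parts[1]))
                    heats.append(float(parts[3]) if len(parts) > 3 and parts[3] else np.nan)
        heats_arr = np.asarray(heats)
        return cls(
            injection_volumes=np.asarray(vols),
            cell_volume=meta["cell_volume_L"],
            cell_conc=meta["cell_conc_M"],
            syringe_conc=meta["syringe_conc_M"],
            temperature=meta.get("temperature_K", 293.15),
            heats=None if np.isnan(heats_arr).all() else heats_arr,
        )


@dataclass(frozen=True)
class OneSiteParams:
    """Parameters of a single class of independent, identical sites."""

    Kd: float          # mol/L
    dH: float          # kcal/mol
    n_sites: float = 1.0

    def __post_init__(self):
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")


# ------------------------------------------------------------- forward model

def _bound_complex(sites: np.ndarray, X: np.ndarray, Kd: float) -> np.ndarray:
    """Closed-form root of PL^2 - (S + X + Kd) PL + S X = 0 (stable form)."""
    b = sites + X + Kd
    disc = b * b - 4.0 * sites * X
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def one_site_isotherm(params: OneSiteParams, schedule: Isotherm) -> np.ndarray:
    """Predicted heats (kcal per mol injectant) for an injection schedule.

    Per injection, total concentrations are updated with the displacement
    dilution correction, the bound complex is the closed-form root of the
    one-site quadratic mass balance, and the evolved heat is
    dH * V0 * (PL_i - PL_{i-1} * (1 - v_i/V0)) normalized by the moles of
    titrant injected.
    """
    M, X = schedule.concentrations()
    v = schedule.injection_volumes
    V0 = schedule.cell_volume
    PL = _bound_complex(params.n_sites * M, X, params.Kd)
    PL_prev = np.concatenate([[0.0], PL[:-1]])
    dcomplex = PL - PL_prev * (1.0 - v / V0)
    moles_injected = schedule.syringe_conc * v
    return params.dH * V0 * dcomplex / moles_injected


def thermodynamics(Kd: float, dH: float, T: float) -> Tuple[float, float]:
    """(dG, dS) from dG = R T ln Kd and dS = (dH - dG)/T.

    dG is in kcal/mol (negative for sub-molar Kd), dS in kcal/(mol K).
    """
    if Kd <= 0 or T <= 0:
        raise ValueError("Kd and T must be positive")
    dG = R_KCAL * T * np.log(Kd)
    return float(dG), float((dH - dG) / T)


# ----------------------------------------------------------------- model fit

class OneSiteModel:
    """Nonlinear least-squares one-site model of an ITC isotherm.

    >>> res = OneSiteModel(isotherm).fit()
    >>> res.Kd, res.dH, res.n_sites, res.dG, res.dS
    """

    def __init__(self, data: Isotherm, discard_first: bool = False):
        if data.heats is None:
            raise ValueError("isotherm carries no measured heats")
        self.data = data
        self.discard_first = discard_first
        self._mask = np.ones(data.n_injections, dtype=bool)
        if discard_first:
            self._mask[0] = False

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        params = OneSiteParams(Kd=float(np.exp(x[0])), dH=float(x[1]),
                               n_sites=float(x[2]))
        pred = one_site_isotherm(params, self.data)
        return (pred - self.data.heats)[self._mask]

    def fit(self, init: Optional[OneSiteParams] = None,
            n_starts: int = 3) -> "OneSiteResults":
        """Fit (Kd, dH, n_sites); Kd is log-parameterized to stay positive.

        ``n_starts`` runs the optimizer from initial Kd guesses spread an
        order of magnitude around the starting point and keeps the best
        optimum, to reduce sensitivity to local minima.
        """
        heats = self.data.heats[self._mask]
        if init is None:
            dh0 = heats[np.argmax(np.abs(heats[: max(2, heats.size // 4)]))]
            if dh0 == 0:
                dh0 = -1.0
            init = OneSiteParams(Kd=self.data.cell_conc / 10.0, dH=float(dh0),
                                 n_sites=1.0)
        factors = [1.0, 0.1, 10.0][:max(1, n_starts)]
        best = None
        lb = [np.log(1e-15), -1e4, 1e-3]
        ub = [np.log(10.0), 1e4, 1e3]
        for f in factors:
            x0 = np.array([np.log(init.Kd * f),
                           init.dH if init.dH != 0 else -1.0,
                           init.n_sites])
            x0[0] = np.clip(x0[0], lb[0], ub[0])
            sol = least_squares(self._residuals, x0, bounds=(lb, ub),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        return self._results(best)

    def _results(self, sol) -> "OneSiteResults":
        x = sol.x
        Kd, dH, n = float(np.exp(x[0])), float(x[1]), float(x[2])
        resid = sol.fun
        dof = resid.size - 3
        rss = float(resid @ resid)
        # parameter covariance from local curvature (Gauss-Newton approx.)
        sds = np.full(3, np.nan)
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * (rss / dof if dof > 0 else np.nan)
            sds = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
        T = self.data.temperature
        dG, dS = thermodynamics(Kd, dH, T)
        return OneSiteResults(
            model=self,
            Kd=Kd, dH=dH, n_sites=n,
            Kd_sd=Kd * float(sds[0]),   # delta method on log Kd
            dH_sd=float(sds[1]), n_sites_sd=float(sds[2]),
            dG=dG, dS=dS, rss=rss,
            converged=bool(sol.success and np.isfinite(sds).all()),
            n_obs=int(resid.size), message=str(sol.message),
        )


@dataclass
class OneSiteResults:
    """Fitted one-site parameters with uncertainties and derived
    thermodynamics; ``dG = R T ln Kd`` and ``dS = (dH - dG)/T`` hold
    exactly for the stored fields."""

    model: OneSiteModel
    Kd: float
    dH: float
    n_sites: float
    Kd_sd: float
    dH_sd: float
    n_sites_sd: float
    dG: float
    dS: float
    rss: float
    converged: bool
    n_obs: int
    message: str = ""

    @property
    def params(self) -> OneSiteParams:
        return OneSiteParams(self.Kd, self.dH, self.n_sites)

    def predicted(self) -> np.ndarray:
        return one_site_isotherm(self.params, self.model.data)

    def summary(self) -> str:
        T = self.model.data.temperature
        lines = [
            "One-site ITC fit" + ("" if self.converged else "  [NOT CONVERGED]"),
            f"  observations: {self.n_obs}   T = {T:.2f} K   RSS = {self.rss:.4g}",
            f"  Kd      = {self.Kd:.4g} M  (s.d. {self.Kd_sd:.2g})",
            f"  dH      = {self.dH:.4g} kcal/mol  (s.d. {self.dH_sd:.2g})",
            f"  n_sites = {self.n_sites:.4g}  (s.d. {self.n_sites_sd:.2g})",
            f"  dG      = {self.dG:.4g} kcal/mol",
            f"  dS      = {self.dS:.4g} kcal/(mol K)  (-T dS = {-T * self.dS:.4g} kcal/mol)",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        import json
        out = {k: getattr(self, k) for k in
               ("Kd", "dH", "n_sites", "Kd_sd", "dH_sd", "n_sites_sd",
                "dG", "dS", "rss", "converged", "n_obs", "message")}
        out["temperature_K"] = self.model.data.temperature
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)

    def plot(self, ax=None):
        """Measured vs fitted heats against the molar ratio."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ratios = self.model.data.molar_ratios()
        ax.plot(ratios, self.model.data.heats, "o", label="measured")
        ax.plot(ratios, self.predicted(), "-", label="one-site fit")
        ax.set_xlabel("molar ratio (titrant : cell)")
        ax.set_ylabel("heat (kcal / mol injectant)")
        ax.legend()
        return ax


def fit_one_site(data: Isotherm, init: Optional[OneSiteParams] = None,
                 discard_first: bool = False) -> OneSiteResults:
    """Functional wrapper around :class:`OneSiteModel`."""
    return OneSiteModel(data, discard_first=discard_first).fit(init=init)
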