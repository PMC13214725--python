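"""Per-protein linear models with empirical-Bayes variance moderation.

This is the quantitative core of the pipeline.  Each protein is fitted by
ordinary least squares against a factorial design (tolerance class x sampling
day by default), residual variances are shrunk toward a common prior by
fitting a scaled inverse chi-square distribution to the observed variances
(method of moments on log s-squared, with the trigamma inversion that is
standard for this family), and contrasts are tested with moderated
t-statistics on d0 + d degrees of freedom:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = (c' beta) / sqrt(s_tilde^2 * c' (X'X)^-1 c)

Benjamini-Hochberg adjustment and the differential-abundance calling rules
(adjusted p < alpha and |log2FC| >= lfc_min; interaction proteins by FDR
alone) complete the stage.

Organised as a statsmodels-style pair: :class:`DifferentialAbundanceModel`
holds data + design and ``fit()`` returns a
:class:`DifferentialAbundanceResults` carrying estimates, moderation
parameters and the contrast/DAP-calling methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .containers import IntensityMatrix, SampleDesign, ValidationError

logger = logging.getLogger("proteoheat")

STANDARD_CONTRASTS = ("baseline_class", "sensitive_day", "tolerant_day", "interaction")


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p(i) = min_{j >= i} p(j) * m / j over the ascending order, capped at
    1; ties share the rank-based value by construction.  NaN inputs
    propagate as NaN and are excluded from m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    q = p[finite]
    if ((q < 0) | (q > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[finite] = res
    return out


# --------------------------------------------------------------------------
# empirical Bayes moderation
# --------------------------------------------------------------------------

@dataclass
class ModerationParams:
    """Scaled inverse chi-square prior on residual variances.

    d0: prior degrees of freedom (np.inf permitted); s0_sq: prior variance
    (log2^2 units); df_residual: per-protein residual degrees of freedom d.
    """

    d0: float
    s0_sq: float
    df_residual: float

    def posterior_var(self, s2: np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        if np.isinf(self.d0):
            return np.full(s2.shape, self.s0_sq)
        if self.d0 == 0:
            return s2.copy()
        d = self.df_residual
        return (self.d0 * self.s0_sq + d * s2) / (self.d0 + d)

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a well-behaved transform)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def ebayes_moderate(s2, d: float, min_proteins: int = 10) -> ModerationParams:
    """Estimate (d0, s0^2) by moment matching on log s^2.

    Under the scaled inverse chi-square prior, s^2 / s0^2 follows an
    F(d, d0) distribution; with e = log(s^2) - digamma(d/2) + log(d/2),
    Var(e) - trigamma(d/2) = trigamma(d0/2) gives d0 by trigamma inversion
    and the mean of e gives s0^2 in closed form.  With fewer than
    ``min_proteins`` positive finite variances moderation is disabled
    (d0 = 0) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < min_proteins:
        warnings.warn(
            f"only {int(ok.sum())} finite residual variances; "
            "moderation disabled (d0 = 0)", stacklevel=2,
        )
        s0 = float(np.median(s2[ok])) if ok.any() else 1.0
        return ModerationParams(d0=0.0, s0_sq=s0, df_residual=float(d))
    z = np.log(s2[ok])
    if np.ptp(z) == 0.0:
        # degenerate spread: no sampling noise to attribute to chi-square
        # variation, so the common value is its own fixed point
        return ModerationParams(d0=np.inf, s0_sq=float(s2[ok][0]), df_residual=float(d))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq, df_residual=float(d))


# --------------------------------------------------------------------------
# design and contrasts
# --------------------------------------------------------------------------

@dataclass
class ContrastSpec:
    """Named coefficient vector over the columns of the design matrix."""

    name: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)


def _design_matrix(design: SampleDesign, sample_ids, model: str):
    """Dummy-coded design matrix (reference = first sorted level)."""
    meta = design.table.loc[sample_ids]
    days = sorted(meta["day"].unique())
    if len(days) != 2:
        raise ValidationError(f"the factorial model expects 2 days, got {days}")
    stress = days[-1]
    day_ind = (meta["day"] == stress).astype(float).to_numpy()
    cols, names = [np.ones(len(meta))], ["Intercept"]
    if model == "class_day":
        classes = sorted(meta["tolerance_class"].unique())
        if len(classes) != 2:
            raise ValidationError(f"class_day model expects 2 classes, got {classes}")
        levels = classes[1:]
        factor = meta["tolerance_class"]
        label = "class"
    elif model == "genotype_day":
        genos = sorted(meta["genotype"].unique())
        levels = genos[1:]
        factor = meta["genotype"]
        label = "genotype"
    else:
        raise ValidationError(f"unknown model {model!r}")
    for lv in levels:
        cols.append((factor == lv).astype(float).to_numpy())
        names.append(f"{label}[{lv}]")
    cols.append(day_ind)
    names.append(f"day[{stress}]")
    for lv in levels:
        cols.append((factor == lv).astype(float).to_numpy() * day_ind)
        names.append(f"{label}[{lv}]:day[{stress}]")
    X = np.column_stack(cols)
    return X, names, stress


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValidationError(f"design matrix is rank-deficient; collinear column(s): {bad}")


class DifferentialAbundanceModel:
    """Factorial OLS model of a (complete or imputed) intensity matrix.

    Parameters
    ----------
    matrix : IntensityMatrix
        Log2-scale matrix with no missing values (run the preprocessing
        chain first); the detection mask travels along untouched for the
        downstream detection-based classifiers.
    design : SampleDesign
    model : {"class_day", "genotype_day"}
        ``class_day`` (default) fits class + day + class:day over all
        samples, treating genotypes within a tolerance class as biological
        replicates; ``genotype_day`` fits genotype-level cells and
        aggregates genotype means to class level in the contrasts.
    """

    def __init__(self, matrix: IntensityMatrix, design: SampleDesign,
                 model: str = "class_day"):
        design.check_matches(matrix)
        if matrix.values.isna().any().any():
            raise ValidationError("model requires a complete (imputed) matrix")
        self.matrix = matrix
        self.design = design
        self.model = model
        self.exog, self.exog_names, self.stress_day = _design_matrix(
            design, matrix.sample_ids, model
        )
        _check_full_rank(self.exog, self.exog_names)

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design_table: pd.DataFrame,
                       model: str = "class_day") -> "DifferentialAbundanceModel":
        m = IntensityMatrix(values, values.notna(), scale_flag="imputed")
        return cls(m, SampleDesign(design_table), model=model)

    # -- contrast construction --------------------------------------------
    def _cell_row(self, level, day) -> np.ndarray:
        """Design row of the mean of one (factor level, day) cell."""
        meta = self.design.table.loc[self.matrix.sample_ids]
        if self.model == "class_day":
            sel = (meta["tolerance_class"] == level) & (meta["day"] == day)
        else:
            sel = (meta["genotype"] == level) & (meta["day"] == day)
        if not sel.any():
            raise ValidationError(f"empty design cell ({level}, day {day})")
        return self.exog[sel.to_numpy()].mean(axis=0)

    def _class_cell_row(self, klass, day) -> np.ndarray:
        """Class-level cell mean; averages genotype cells under genotype_day."""
        if self.model == "class_day":
            return self._cell_row(klass, day)
        meta = self.design.table
        genos = sorted(meta.loc[meta["tolerance_class"] == klass, "genotype"].unique())
        return np.mean([self._cell_row(g, day) for g in genos], axis=0)

    def contrast_spec(self, name: str) -> ContrastSpec:
        """Coefficient vector for one of the standard named contrasts."""
        days = sorted(self.design.table["day"].unique())
        d0_, d6 = days[0], days[-1]
        cell = self._class_cell_row
        if name == "baseline_class":
            c = cell("tolerant", d0_) - cell("sensitive", d0_)
        elif name == "sensitive_day":
            c = cell("sensitive", d6) - cell("sensitive", d0_)
        elif name == "tolerant_day":
            c = cell("tolerant", d6) - cell("tolerant", d0_)
        elif name == "interaction":
            c = (cell("tolerant", d6) - cell("tolerant", d0_)) - (
                cell("sensitive", d6) - cell("sensitive", d0_))
        else:
            raise ValidationError(
                f"unknown contrast {name!r}; expected one of {STANDARD_CONTRASTS}")
        return ContrastSpec(name, c)

    # -- fitting ------------------------------------------------------------
    def fit(self, moderate: bool = True, d0: float | None = None,
            s0_sq: float | None = None) -> "DifferentialAbundanceResults":
        """OLS per protein, then empirical-Bayes variance moderation.

        ``d0``/``s0_sq`` override the estimated prior (d0=0 disables
        moderation, d0=np.inf gives full shrinkage to s0_sq).
        """
        X = self.exog
        Y = self.matrix.values.to_numpy()  # proteins x samples
        n, p = X.shape
        df_resid = n - p
        if df_resid <= 0:
            raise ValidationError(f"no residual degrees of freedom (n={n}, p={p})")
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = Y @ (X @ xtx_inv)          # proteins x p
        resid = Y - coef @ X.T
        s2 = (resid**2).sum(axis=1) / df_resid

        floored = s2 < np.finfo(float).eps * max(1.0, float(np.nanmax(s2, initial=1.0)))
        if floored.any():
            s2 = np.where(floored, np.finfo(float).eps, s2)
            logger.info("fit: floored %d zero residual variances", int(floored.sum()))

        if not moderate:
            params = ModerationParams(d0=0.0, s0_sq=float(np.median(s2)),
                                      df_residual=float(df_resid))
        elif d0 is not None:
            s0 = float(s0_sq) if s0_sq is not None else float(np.median(s2))
            params = ModerationParams(d0=float(d0), s0_sq=s0,
                                      df_residual=float(df_resid))
        else:
            params = ebayes_moderate(s2, df_resid)
            if s0_sq is not None:
                params.s0_sq = float(s0_sq)
        return DifferentialAbundanceResults(
            model=self, coefficients=coef, s2=s2, xtx_inv=xtx_inv,
            moderation=params, var_floored=floored,
        )


@dataclass
class DifferentialAbundanceResults:
    """Fitted per-protein estimates plus moderation parameters."""

    model: DifferentialAbundanceModel
    coefficients: np.ndarray          # proteins x design columns
    s2: np.ndarray                    # raw residual variances
    xtx_inv: np.ndarray
    moderation: ModerationParams
    var_floored: np.ndarray = field(repr=False, default=None)

    @property
    def protein_ids(self) -> pd.Index:
        return self.model.matrix.protein_ids

    @property
    def s2_post(self) -> np.ndarray:
        return self.moderation.posterior_var(self.s2)

    def contrast(self, spec) -> pd.DataFrame:
        """Moderated-t table for a contrast (name or ContrastSpec).

        Columns: log2fc, se, t, df, p, adj_p — indexed by protein id.
        """
        if isinstance(spec, str):
            spec = self.model.contrast_spec(spec)
        c = spec.coefficients
        if c.shape != (self.coefficients.shape[1],):
            raise ValidationError(
                f"contrast length {c.shape} does not match design columns "
                f"({self.coefficients.shape[1]})")
        effect = self.coefficients @ c
        unit_var = float(c @ self.xtx_inv @ c)
        se = np.sqrt(self.s2_post * unit_var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        df_total = self.moderation.df_total
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        out = pd.DataFrame(
            {"log2fc": effect, "se": se, "t": t, "df": df_total, "p": p},
            index=self.protein_ids,
        )
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out.insert(0, "contrast", spec.name)
        return out

    def call_daps(self, contrast="sensitive_day", alpha: float = 0.05,
                  lfc_min: float = 1.0) -> pd.DataFrame:
        """Differential-abundance calls for one contrast.

        A protein is significant iff adjusted p < alpha AND |log2FC| >=
        lfc_min (the boundary |log2FC| = lfc_min counts).  ``track`` is
        initialised to ``none`` and filled by the detection classifier.
        """
        tab = self.contrast(contrast)
        tab["significant"] = (tab["adj_p"] < alpha) & (tab["log2fc"].abs() >= lfc_min)
        tab["direction"] = np.where(tab["log2fc"] >= 0, "up", "down")
        tab["track"] = "none"
        return tab

    def interaction_daps(self, fdr: float = 0.05) -> pd.DataFrame:
        """Candidate genotype x day interaction proteins (FDR rule only).

        Flags proteins with interaction adjusted p < fdr; no fold-change
        gate is applied to the interaction call.
        """
        tab = self.contrast("interaction")
        tab["significant"] = tab["adj_p"] < fdr
        tab["direction"] = np.where(tab["log2fc"] >= 0, "up", "down")
        tab["track"] = "none"
        return tab

    def summary(self, contrasts=STANDARD_CONTRASTS, alpha: float = 0.05,
                lfc_min: float = 1.0) -> str:
        """Human-readable fit summary across the standard contrasts."""
        lines = [
            "Differential abundance fit",
            "=" * 62,
            f"proteins: {len(self.protein_ids)}   samples: {self.model.matrix.n_samples}"
            f"   model: {self.model.model}",
            f"residual df d = {self.moderation.df_residual:g}   "
            f"prior d0 = {self.moderation.d0:.4g}   "
            f"prior s0^2 = {self.moderation.s0_sq:.4g}",
            "-" * 62,
            f"{'contrast':<18}{'n sig':>8}{'up':>8}{'down':>8}",
        ]
        for name in contrasts:
            if name == "interaction":
                tab = self.interaction_daps(fdr=alpha)
            else:
                tab = self.call_daps(name, alpha=alpha, lfc_min=lfc_min)
            sig = tab[tab["significant"]]
            lines.append(
                f"{name:<18}{len(sig):>8}{(sig['direction'] == 'up').sum():>8}"
                f"{(sig['direction'] == 'down').sum():>8}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)
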