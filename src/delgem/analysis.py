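"""Hit characterization: novelty, property statistics, embedding, IC50 fitting.

Covers the post-campaign analyses run on nomination sets: Tanimoto novelty
against the reference binder, two-sample significance tests on descriptor
panels between cycles, 2-D chemical-space embedding of fingerprints, and
four-parameter-logistic (4PL) fitting of TR-FRET-style dose-response data
with per-replicate mean +/- SD aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.manifold import TSNE

from . import chem
from .chem import Fingerprint, Molecule, PropertyPanel
from .errors import ConfigError, FitError, StatError


# --------------------------------------------------------------------------
# Novelty
# --------------------------------------------------------------------------

def novelty_profile(
    mols: Sequence[Molecule],
    reference: Molecule,
    radius: int = chem.DEFAULT_RADIUS,
    n_bits: int = chem.DEFAULT_N_BITS,
) -> tuple[np.ndarray, float]:
    """Tanimoto similarity of each molecule to the reference, plus the maximum.

    A low maximum indicates the set is structurally novel relative to the
    reference compound. Invariant to the order of ``mols``.
    """
    if len(mols) == 0:
        raise ConfigError("novelty_profile requires a non-empty molecule list")
    ref_fp = chem.fingerprint(reference, radius, n_bits)
    sims = np.array(
        [chem.tanimoto(chem.fingerprint(m, radius, n_bits), ref_fp) for m in mols]
    )
    return sims, float(sims.max())


# --------------------------------------------------------------------------
# Property significance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    property_name: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_two_tailed: float
    equal_var: bool
    n_a: int
    n_b: int


def compare_property(
    group_a: Sequence[PropertyPanel],
    group_b: Sequence[PropertyPanel],
    property_name: str,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample two-tailed t-test on one descriptor between two panels.

    Welch (unequal variance) by default; pass ``equal_var=True`` for the
    pooled Student variant. Symmetric up to the sign of t.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise StatError("each group needs >= 3 members")
    a = np.array([p[property_name] for p in group_a], dtype=float)
    b = np.array([p[property_name] for p in group_b], dtype=float)
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        # degenerate identical constant groups: no evidence of difference
        return ComparisonResult(property_name, float(a.mean()), float(b.mean()),
                                0.0, 1.0, equal_var, len(a), len(b))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        property_name=property_name,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        p_two_tailed=float(res.pvalue),
        equal_var=equal_var,
        n_a=len(a),
        n_b=len(b),
    )


# --------------------------------------------------------------------------
# Chemical-space embedding
# --------------------------------------------------------------------------

def embed_2d(
    fps: Sequence[Fingerprint], perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """t-SNE embedding of fingerprints to 2-D; one row per input, order kept.

    Deterministic for a fixed seed (single-threaded, PCA initialization).
    """
    n = len(fps)
    if n < 5:
        raise ConfigError(f"embed_2d needs >= 5 fingerprints, got {n}")
    if perplexity >= n / 3:
        raise ConfigError(f"perplexity {perplexity} too large for n={n} (need < n/3)")
    widths = {fp.n_bits for fp in fps}
    if len(widths) != 1:
        raise ConfigError(f"mixed fingerprint widths: {sorted(widths)}")
    X = np.stack([np.unpackbits(fp.packed, count=fp.n_bits) for fp in fps]).astype(np.float32)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    return tsne.fit_transform(X)


# --------------------------------------------------------------------------
# Dose-response fitting
# --------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """One replicate's concentration/response series (signal fractions)."""

    concentrations_uM: np.ndarray
    responses: np.ndarray
    replicate_id: str = "rep1"
    compound_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations_uM.shape != self.responses.shape:
            raise ConfigError("concentration and response lengths differ")
        if len(self.concentrations_uM) < 5:
            raise ConfigError("need >= 5 concentration points for fitting")
        if np.any(self.concentrations_uM <= 0):
            raise ConfigError("concentrations must be positive")


@dataclass(frozen=True)
class FitResult:
    """Fitted 4PL parameters with standard errors and residuals."""

    bottom: float
    top: float
    ic50_uM: float
    hill: float
    se: dict  # parameter name -> standard error (may be nan if singular)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, conc_uM: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(conc_uM, dtype=float),
                       self.bottom, self.top, self.ic50_uM, self.hill)


def four_pl(conc: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """response = bottom + (top - bottom) / (1 + (conc / ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def _fit_model(conc, bottom, top, log_ic50, hill):
    return four_pl(conc, bottom, top, 10.0 ** log_ic50, hill)


def fit_4pl(curve: DoseResponse) -> FitResult:
    """Least-squares 4PL fit of one dose-response replicate.

    The IC50 is optimized on a log10 scale for conditioning. Initial values:
    bottom/top from the extreme responses, IC50 from the concentration whose
    response is nearest the half-signal, Hill slope 1.

    Raises
    ------
    FitError
        If the optimizer fails or the response span is too narrow
        (< 30% of the fitted bottom-top range carries no curvature signal).
    """
    conc = curve.concentrations_uM
    resp = curve.responses
    span = resp.max() - resp.min()
    if span <= 0:
        raise FitError("flat responses: nothing to fit")
    top0 = float(resp.max())
    bottom0 = float(resp.min())
    half = (top0 + bottom0) / 2.0
    ic50_0 = float(conc[np.argmin(np.abs(resp - half))])
    p0 = [bottom0, top0, np.log10(ic50_0), 1.0]
    lo = [bottom0 - 2 * span, top0 - 2 * span, np.log10(conc.min()) - 3, 0.05]
    hi = [bottom0 + 2 * span, top0 + 2 * span, np.log10(conc.max()) + 3, 10.0]
    try:
        popt, pcov = optimize.curve_fit(
            _fit_model, conc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_ic50, hill = popt
    fitted_span = abs(top - bottom)
    if fitted_span > 0 and span < 0.3 * fitted_span:
        raise FitError(
            f"responses span {span:.3g}, < 30% of fitted range {fitted_span:.3g}; "
            "IC50 is unconstrained"
        )
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    ic50 = float(10.0 ** log_ic50)
    se = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        # delta method: d(ic50)/d(log_ic50) = ln(10) * ic50
        "ic50_uM": float(perr[2] * np.log(10.0) * ic50),
        "hill": float(perr[3]),
    }
    residuals = resp - _fit_model(conc, *popt)
    if not np.all(np.isfinite(residuals)):
        raise FitError("non-finite residuals after fit")
    return FitResult(bottom=float(bottom), top=float(top), ic50_uM=ic50,
                     hill=float(hill), se=se, residuals=residuals)


def aggregate_ic50(fits: Sequence[FitResult]) -> tuple[float, float, int]:
    """Mean +/- SD of per-replicate IC50 fits (the reporting convention
    for replicate displacement assays). Returns (mean_uM, sd_uM, n)."""
    if len(fits) == 0:
        raise StatError("no fits to aggregate")
    vals = np.array([f.ic50_uM for f in fits], dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, len(vals)


def fit_dose_response_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every (compound, replicate) curve in a tidy assay table.

    Expects columns ``compound_id, replicate, concentration_uM, signal``.
    Returns one row per compound: ``compound_id, ic50_uM, sd_uM,
    n_replicates``. Replicates whose fit fails are dropped with the count
    reflected in ``n_replicates``; a compound with no convergent replicate
    raises :class:`FitError`.
    """
    required = {"compound_id", "replicate", "concentration_uM", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"dose-response table missing columns: {sorted(missing)}")
    rows = []
    for compound, sub in df.groupby("compound_id", sort=True):
        fits = []
        for rep, curve in sub.groupby("replicate", sort=True):
            dr = DoseResponse(
                concentrations_uM=curve["concentration_uM"].to_numpy(),
                responses=curve["signal"].to_numpy(),
                replicate_id=str(rep),
                compound_id=str(compound),
            )
            try:
                fits.append(fit_4pl(dr))
            except FitError:
                continue
        if not fits:
            raise FitError(f"no replicate of {compound} produced a convergent 4PL fit")
        mean, sd, n = aggregate_ic50(fits)
        rows.append({"compound_id": compound, "ic50_uM": mean, "sd_uM": sd, "n_replicates": n})
    return pd.DataFrame(rows)
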