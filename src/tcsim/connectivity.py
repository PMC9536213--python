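"""Distance-dependent connection-probability rules.

Connection probabilities are estimated per pathway from stochastic connectome
instances in 50-um distance bins (centres 25, 75, ..., 375 um, half-width
25 um), averaged across instances, and fitted with one of three families:

- ``exponential``    p(d) = A * exp(-d / lam)
- ``exp_linsat``     p(d) = min(p_sat, A * exp(-d / lam))
- ``gaussian``       p(d) = A * exp(-(d - mu)^2 / (2 sigma^2))

The family with the smallest unweighted sum of squared errors over populated
bins is selected; ties break toward fewer parameters, then by the order
exponential < exp_linsat < gaussian.  All distances are 2D somatic distances
in the horizontal XZ plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_BIN_CENTERS = np.arange(25.0, 376.0, 50.0)  # 8 bins
DEFAULT_BIN_HALFWIDTH = 25.0

FORMS = ("exponential", "exp_linsat", "gaussian")
_N_PARAMS = {"exponential": 2, "exp_linsat": 3, "gaussian": 3}


def evaluate_form(form: str, params, d):
    """Evaluate a probability family at distance(s) d, clipped to [0, 1]."""
    d = np.asarray(d, dtype=float)
    if form == "exponential":
        A, lam = params
        p = A * np.exp(-d / lam)
    elif form == "exp_linsat":
        A, lam, p_sat = params
        p = np.minimum(p_sat, A * np.exp(-d / lam))
    elif form == "gaussian":
        A, mu, sigma = params
        p = A * np.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
    else:
        raise ValueError(f"unknown probability form {form!r}")
    return np.clip(p, 0.0, 1.0)


@dataclass
class DistanceBinProfile:
    """Binned connection probabilities for one pathway."""

    bin_centers: np.ndarray
    bin_halfwidth: float
    probabilities: np.ndarray      # per present bin; NaN where no pairs
    pair_counts: np.ndarray        # ordered pairs per bin
    per_instance: np.ndarray | None = None  # (n_instances, n_bins) or None
    # mean pair distance per bin: the unbiased abscissa for fitting (pair
    # density grows ~linearly with distance, so the nominal centre
    # overstates short-range probabilities)
    effective_distance: np.ndarray | None = None

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.probabilities)

    def fit_abscissa(self) -> np.ndarray:
        if self.effective_distance is None:
            return self.bin_centers
        return np.where(np.isnan(self.effective_distance), self.bin_centers,
                        self.effective_distance)


@dataclass
class FitModel:
    """A fitted probability family."""

    form: str
    params: tuple
    sse: float
    converged: bool = True
    diagnostic: str = ""

    def __call__(self, d):
        return evaluate_form(self.form, self.params, d)


@dataclass
class PathwayRule:
    """Fitted rule plus mean synapses per connection for a directed pathway."""

    pre_m_type: str
    post_m_type: str
    fit: FitModel
    mean_nsyn: float = 1.0

    def __post_init__(self):
        if self.mean_nsyn < 1:
            raise ValueError("mean_nsyn must be >= 1")

    def probability(self, d):
        return self.fit(d)


def xz_distances(pre_xyz: np.ndarray, post_xyz: np.ndarray) -> np.ndarray:
    """(n_pre, n_post) matrix of horizontal (XZ-plane) somatic distances."""
    dx = pre_xyz[:, 0:1] - post_xyz[None, :, 0]
    dz = pre_xyz[:, 2:3] - post_xyz[None, :, 2]
    return np.sqrt(dx**2 + dz**2)


def estimate_bin_probabilities(
    edges: pd.DataFrame, pre_xyz: np.ndarray, post_xyz: np.ndarray,
    bin_centers=DEFAULT_BIN_CENTERS, bin_halfwidth=DEFAULT_BIN_HALFWIDTH,
    same_population: bool = False,
) -> DistanceBinProfile:
    """Per-bin connection probability over ordered pairs of one pathway.

    ``edges`` needs columns ``pre`` and ``post`` (indices into the placement
    arrays).  With ``same_population`` the diagonal (self-pairs) is excluded
    from the denominator.
    """
    if len(pre_xyz) == 0 or len(post_xyz) == 0:
        raise ValueError("empty placement")
    bin_centers = np.asarray(bin_centers, dtype=float)
    dmat = xz_distances(pre_xyz, post_xyz)
    valid = np.ones_like(dmat, dtype=bool)
    if same_population:
        np.fill_diagonal(valid, False)
    conn = np.zeros_like(dmat, dtype=bool)
    if len(edges):
        conn[edges["pre"].to_numpy(), edges["post"].to_numpy()] = True
    probs = np.full(len(bin_centers), np.nan)
    counts = np.zeros(len(bin_centers), dtype=int)
    eff = np.full(len(bin_centers), np.nan)
    for i, c in enumerate(bin_centers):
        mask = valid & (np.abs(dmat - c) <= bin_halfwidth)
        n = int(mask.sum())
        counts[i] = n
        if n > 0:
            probs[i] = conn[mask].mean()
            eff[i] = dmat[mask].mean()
    return DistanceBinProfile(bin_centers, float(bin_halfwidth), probs, counts,
                              effective_distance=eff)


def average_across_instances(profiles: list[DistanceBinProfile]) -> DistanceBinProfile:
    """Arithmetic mean per bin over instances where the bin is present."""
    ref = profiles[0]
    for p in profiles[1:]:
        if (len(p.bin_centers) != len(ref.bin_centers)
                or not np.allclose(p.bin_centers, ref.bin_centers)
                or p.bin_halfwidth != ref.bin_halfwidth):
            raise ValueError("mismatched binning across instances")
    stack = np.vstack([p.probabilities for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stack, axis=0)
        effs = np.vstack([
            p.effective_distance if p.effective_distance is not None
            else np.full(len(ref.bin_centers), np.nan) for p in profiles])
        eff = np.nanmean(effs, axis=0)
    counts = np.sum([p.pair_counts for p in profiles], axis=0)
    return DistanceBinProfile(ref.bin_centers.copy(), ref.bin_halfwidth,
                              mean, counts, per_instance=stack,
                              effective_distance=eff)


def _fit_one(form: str, d: np.ndarray, p: np.ndarray) -> FitModel:
    pmax = float(p.max())
    if pmax == 0.0:
        # degenerate all-zero profile: zero-amplitude member of each family
        params = {"exponential": (0.0, 100.0),
                  "exp_linsat": (0.0, 100.0, 0.0),
                  "gaussian": (0.0, 0.0, 100.0)}[form]
        return FitModel(form, params, 0.0)
    span = float(d.max() - d.min()) or 1.0
    if form == "exponential":
        f = lambda x, A, lam: A * np.exp(-x / lam)
        p0, lb, ub = (pmax, span / 2), (0, 1e-3), (1.0, 1e5)
    elif form == "exp_linsat":
        f = lambda x, A, lam, p_sat: np.minimum(p_sat, A * np.exp(-x / lam))
        p0 = (min(1.0, pmax * 2), span / 2, pmax)
        lb, ub = (0, 1e-3, 0), (10.0, 1e5, 1.0)
    else:  # gaussian; centre offset mu >= 0, amplitude <= 1
        mu0 = float(d[np.argmax(p)])
        f = lambda x, A, mu, sigma: A * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
        p0, lb, ub = (pmax, mu0, span / 2), (0, 0, 1e-3), (1.0, 1e4, 1e5)
    try:
        popt, _ = curve_fit(f, d, p, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FitModel(form, tuple(p0), float(np.sum((p - f(d, *p0)) ** 2)),
                        converged=False, diagnostic=str(exc))
    if not np.all(np.isfinite(popt)):
        return FitModel(form, tuple(p0), np.inf, converged=False,
                        diagnostic="non-finite parameters")
    resid = p - evaluate_form(form, popt, d)
    return FitModel(form, tuple(float(x) for x in popt), float(np.sum(resid**2)))


def fit_probability_model(profile: DistanceBinProfile, form: str) -> FitModel:
    """Unweighted least-squares fit of one family to the populated bins."""
    if form not in FORMS:
        raise ValueError(f"unknown probability form {form!r}")
    ok = profile.present
    d, p = profile.fit_abscissa()[ok], profile.probabilities[ok]
    if ok.sum() < _N_PARAMS[form]:
        raise ValueError(
            f"{int(ok.sum())} populated bins cannot constrain a {form} fit")
    return _fit_one(form, d, p)


#: a simpler family wins if its SSE is within this relative margin of the
#: best fit — soaks up the SSE a free extra parameter gains on pure noise
PARSIMONY_REL_TOL = 0.3


def select_best_fit(profile: DistanceBinProfile,
                    forms=FORMS) -> FitModel:
    """Fit all families and return the best one, with a parsimony rule.

    The candidate with minimal SSE defines the benchmark; among all
    candidates whose SSE is within ``PARSIMONY_REL_TOL`` of it, the one with
    fewest parameters wins (remaining ties break by the family order
    exponential < exp_linsat < gaussian).  Structural misfit (a wrong
    family) exceeds the margin by orders of magnitude, while the margin
    absorbs the spurious SSE advantage an extra free parameter earns on
    sampling noise.
    """
    fits = []
    for i, form in enumerate(forms):
        try:
            fits.append((i, fit_probability_model(profile, form)))
        except ValueError:
            continue
    usable = [(i, f) for i, f in fits if f.converged]
    if not usable:
        raise RuntimeError("all probability fits failed for this pathway")
    best_sse = min(f.sse for _, f in usable)
    cutoff = best_sse * (1.0 + PARSIMONY_REL_TOL) + 1e-12
    admitted = [(i, f) for i, f in usable if f.sse <= cutoff]
    return min(admitted, key=lambda t: (_N_PARAMS[t[1].form], t[0]))[1]


def expected_connection_count(rule: PathwayRule, pre_xyz: np.ndarray,
                              post_xyz: np.ndarray,
                              same_population: bool = False) -> float:
    """Sum of p(d_ij) over ordered eligible pairs (no self-connections)."""
    dmat = xz_distances(pre_xyz, post_xyz)
    p = rule.probability(dmat)
    if same_population:
        np.fill_diagonal(p, 0.0)
    return float(p.sum())


def save_rules(rules: list[PathwayRule], path: str | Path) -> None:
    """Serialize fitted rules to a versioned TSV."""
    rows = [{
        "pre_m_type": r.pre_m_type, "post_m_type": r.post_m_type,
        "form": r.fit.form,
        "params": ",".join(f"{x:.8g}" for x in r.fit.params),
        "sse": r.fit.sse, "mean_nsyn": r.mean_nsyn,
    } for r in rules]
    with open(path, "w") as fh:
        fh.write("# tcsim pathway rules v1\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def load_rules(path: str | Path) -> list[PathwayRule]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [PathwayRule(
        pre_m_type=row["pre_m_type"], post_m_type=row["post_m_type"],
        fit=FitModel(row["form"],
                     tuple(float(x) for x in str(row["params"]).split(",")),
                     float(row["sse"])),
        mean_nsyn=float(row["mean_nsyn"]),
    ) for _, row in df.iterrows()]
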