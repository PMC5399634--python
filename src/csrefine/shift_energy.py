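"""Bayesian chemical-shift agreement energy and evaluation statistics.

The agreement between predicted isotropic shieldings sigma and measured
shifts delta is modeled per atom type j as a linear calibration with
zero-centered normal noise:

    delta_ij = a_j * sigma_ij + b_j + eps,   eps ~ N(0, s_j^2)

Slope and offset (a_j, b_j) carry flat non-informative priors and are
marginalized analytically (the Gaussian integral is exact); the error
scale s_j carries a Jeffreys prior pi(s) ~ 1/s and is left to be sampled
by MCMC.  The resulting pseudo-energy, in units of k_B T,

    E_j = (N_j - 2) ln s_j + RSS_min,j / (2 s_j^2)
          + 1/2 ln(N_j * Sxx_j) + (N_j/2 - 1) ln(2 pi) + ln s_j

with Sxx_j the centered sum of squares of sigma, acts as the
data-restraint term of the hybrid energy.  The closed form is validated
against direct 2-D quadrature (``numerical_marginal_oracle``).

The module also houses the evaluation statistics: per-type RMSD / Pearson
r on secondary (random-coil-subtracted) shifts / regression slope with
generalized-ESD outlier removal, the unit-less per-residue error epsilon,
amino-acid-type offsets, and ensemble shielding averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .structure_io import ATOM_TYPES, RandomCoilTable

LOG_2PI = math.log(2.0 * math.pi)


class ShiftEnergyError(ValueError):
    pass


@dataclass
class ShiftDataset:
    """Matched (sigma, delta) pairs grouped by atom type.

    ``data`` maps atom type -> dict with aligned arrays ``sigma``,
    ``delta`` and ``residues`` (1-based indices).
    """

    data: dict

    @classmethod
    def from_pairs(cls, sigma_map: dict, pairs) -> "ShiftDataset":
        """Build from a predictor output map {(res, type): sigma} and
        matched (res, type, delta) pairs; pairs without a prediction are
        dropped."""
        grouped = {t: {"sigma": [], "delta": [], "residues": []} for t in ATOM_TYPES}
        for res, at, delta in pairs:
            sig = sigma_map.get((res, at))
            if sig is None:
                continue
            grouped[at]["sigma"].append(sig)
            grouped[at]["delta"].append(delta)
            grouped[at]["residues"].append(res)
        data = {}
        for at, g in grouped.items():
            if g["residues"]:
                data[at] = {
                    "sigma": np.asarray(g["sigma"], dtype=float),
                    "delta": np.asarray(g["delta"], dtype=float),
                    "residues": np.asarray(g["residues"], dtype=int),
                }
        return cls(data=data)

    def counts(self) -> dict:
        return {at: len(g["delta"]) for at, g in self.data.items()}

    def __len__(self):
        return sum(len(g["delta"]) for g in self.data.values())


@dataclass
class CalibrationState:
    """Per-atom-type slope, offset and error scale.

    When ``marginalized`` is True the (a, b) entries are the data-derived
    plug-in values, kept for reporting only.
    """

    a: dict
    b: dict
    s: dict
    marginalized: bool = True

    def __post_init__(self):
        for at, v in self.s.items():
            if v <= 0:
                raise ShiftEnergyError(f"error scale for {at} must be positive")


@dataclass
class EnergyBreakdown:
    total: float
    per_type: dict = field(default_factory=dict)
    chi2: dict = field(default_factory=dict)
    a_hat: dict = field(default_factory=dict)
    b_hat: dict = field(default_factory=dict)
    rss: dict = field(default_factory=dict)
    dropped: tuple = ()


@dataclass
class EvaluationReport:
    """Per-type accuracy statistics and per-residue epsilon."""

    rmsd: dict = field(default_factory=dict)
    pearson_r: dict = field(default_factory=dict)
    slope: dict = field(default_factory=dict)
    n_used: dict = field(default_factory=dict)
    outliers: dict = field(default_factory=dict)
    epsilon: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["atom_type\tn\trmsd_ppm\tpearson_r\tslope\tn_outliers"]
        for at in ATOM_TYPES:
            if at in self.rmsd:
                lines.append(
                    f"{at}\t{self.n_used[at]}\t{self.rmsd[at]:.4f}\t"
                    f"{self.pearson_r[at]:.4f}\t{self.slope[at]:.4f}\t"
                    f"{int(np.sum(self.outliers[at]))}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Core estimators

def ls_slope_offset(sigma, delta):
    """Least-squares calibration line delta ~ a*sigma + b.

    Returns (a_hat, b_hat, RSS_min).  a_hat is the mean-centered slope
    Sxy/Sxx and b_hat = mean(delta) - a_hat*mean(sigma).
    """
    sigma = np.asarray(sigma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if sigma.shape != delta.shape:
        raise ShiftEnergyError("sigma and delta must have equal length")
    if len(sigma) < 3:
        raise ShiftEnergyError("need at least 3 points for calibration")
    ds = sigma - sigma.mean()
    sxx = float(ds @ ds)
    if sxx < 1e-12 * max(1.0, float(sigma @ sigma)):
        raise ShiftEnergyError("degenerate calibration: sigma is constant")
    a = float(ds @ (delta - delta.mean())) / sxx
    b = float(delta.mean() - a * sigma.mean())
    resid = delta - a * sigma - b
    return a, b, float(resid @ resid)


def chi_squared(delta_pred, delta_exp) -> float:
    """Sum of squared deviations between predicted and measured shifts."""
    delta_pred = np.asarray(delta_pred, dtype=float)
    delta_exp = np.asarray(delta_exp, dtype=float)
    if delta_pred.shape != delta_exp.shape:
        raise ShiftEnergyError("length mismatch")
    r = delta_exp - delta_pred
    return float(r @ r)


def _marginal_type_energy(sigma, delta, s):
    """Closed-form per-type energy in k_B T units (full constants kept)."""
    n = len(sigma)
    a, b, rss = ls_slope_offset(sigma, delta)
    ds = sigma - sigma.mean()
    sxx = float(ds @ ds)
    e = ((n - 2) * math.log(s) + rss / (2.0 * s * s)
         + 0.5 * math.log(n * sxx) + (n / 2.0 - 1.0) * LOG_2PI
         + math.log(s))
    return e, a, b, rss


def marginal_cs_energy(data: ShiftDataset, s: dict, temperature: float = 300.0,
                       min_points: int = 3) -> EnergyBreakdown:
    """Chemical-shift pseudo-energy with (a, b) marginalized, in k_B T units.

    Types with fewer than ``min_points`` shifts (two parameters cannot be
    marginalized from fewer than 3 points) or a constant sigma are
    dropped with a warning; if every type drops out this is an error.
    """
    per_type, chi2, a_hat, b_hat, rss_map = {}, {}, {}, {}, {}
    dropped = []
    for at, g in data.data.items():
        sigma, delta = g["sigma"], g["delta"]
        if len(sigma) < min_points:
            warnings.warn(f"atom type {at}: only {len(sigma)} shifts, dropped "
                          f"from the energy (need >= {min_points})")
            dropped.append(at)
            continue
        if at not in s:
            raise ShiftEnergyError(f"no error scale supplied for atom type {at}")
        try:
            e, a, b, rss = _marginal_type_energy(sigma, delta, float(s[at]))
        except ShiftEnergyError:
            warnings.warn(f"atom type {at}: constant sigma, dropped from the energy")
            dropped.append(at)
            continue
        per_type[at] = e
        a_hat[at], b_hat[at], rss_map[at] = a, b, rss
        chi2[at] = chi_squared(a * sigma + b, delta)
    if not per_type:
        raise ShiftEnergyError("no atom type has enough shifts for the energy")
    return EnergyBreakdown(total=float(sum(per_type.values())), per_type=per_type,
                           chi2=chi2, a_hat=a_hat, b_hat=b_hat, rss=rss_map,
                           dropped=tuple(dropped))


def numerical_marginal_oracle(sigma, delta, s, temperature: float = 300.0,
                              half_width_sds: float = 12.0) -> float:
    """-ln of the (a, b)-integral of the Gaussian likelihood times the
    Jeffreys prior 1/s, by adaptive 2-D quadrature, in k_B T units.

    Independent numerical check of ``marginal_cs_energy``; integrates in
    coordinates centered on the least-squares solution with bounds wide
    enough that the boundary likelihood is negligible.
    """
    sigma = np.asarray(sigma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = len(sigma)
    a0, b0, rss0 = ls_slope_offset(sigma, delta)
    ds = sigma - sigma.mean()
    sxx = float(ds @ ds)
    # Integrate over (slope, offset-at-centroid): b = w - a*mean(sigma),
    # a unit-Jacobian change of variables that decorrelates the (a, b)
    # posterior (in raw coordinates the ellipse is extremely elongated
    # whenever mean(sigma) is large, which defeats adaptive quadrature).
    sd_a = s / math.sqrt(sxx)
    sd_w = s / math.sqrt(n)
    w0 = b0 + a0 * sigma.mean()

    def integrand(w, a):
        resid = delta - (a0 + a) * sigma - ((w0 + w) - (a0 + a) * sigma.mean())
        return math.exp(-(float(resid @ resid) - rss0) / (2.0 * s * s))

    val, err = integrate.dblquad(
        integrand, -half_width_sds * sd_a, half_width_sds * sd_a,
        lambda a: -half_width_sds * sd_w, lambda a: half_width_sds * sd_w,
        epsabs=1e-14, epsrel=1e-11)
    if not np.isfinite(val) or val <= 0 or (err > 1e-7 * val):
        raise ShiftEnergyError("non-convergent quadrature in marginal oracle")
    # restore the factored-out peak likelihood and normalization, add prior
    log_integral = math.log(val) - rss0 / (2.0 * s * s) - (n / 2.0) * (
        LOG_2PI + 2.0 * math.log(s))
    return -(log_integral + math.log(1.0 / s))


def hybrid_energy(e_ff: float, data: ShiftDataset, s: dict,
                  temperature: float = 300.0, allow_empty: bool = False) -> float:
    """Force-field energy plus the marginalized chemical-shift energy.

    There is no explicit restraint weight: the per-type error scales s_j
    set the weight of the data probabilistically.
    """
    if not np.isfinite(e_ff):
        raise ShiftEnergyError("non-finite force-field energy")
    if len(data) == 0:
        if allow_empty:
            return float(e_ff)
        raise ShiftEnergyError("empty shift dataset (pass allow_empty=True to permit)")
    return float(e_ff) + marginal_cs_energy(data, s, temperature).total


def predict_shifts(calibration: CalibrationState, sigma_map: dict) -> dict:
    """delta_pred = a_j sigma + b_j for every (residue, type) key."""
    out = {}
    for (res, at), sig in sigma_map.items():
        if at not in calibration.a or at not in calibration.b:
            raise ShiftEnergyError(f"calibration missing atom type {at}")
        out[(res, at)] = calibration.a[at] * sig + calibration.b[at]
    return out


# ---------------------------------------------------------------------------
# Outlier handling and statistics

def esd_outlier_filter(residuals, alpha: float = 0.05,
                       max_outliers: int | None = None) -> np.ndarray:
    """Rosner's generalized extreme studentized deviate test.

    Returns a boolean mask (True = outlier).  Iteratively removes the
    most extreme studentized point; the test statistic R_i is compared
    with the critical value lambda_i from the t-distribution and all
    points up to the largest i with R_i > lambda_i are flagged.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 10:
        raise ShiftEnergyError("generalized ESD needs at least 10 points")
    if max_outliers is None:
        max_outliers = max(1, math.ceil(0.1 * n))
    if not 1 <= max_outliers < n / 2:
        raise ShiftEnergyError("max_outliers must be in [1, n/2)")
    remaining = np.arange(n)
    removed = []
    stats_r, lams = [], []
    for i in range(1, max_outliers + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd < 1e-12 * max(1.0, np.abs(sub).max()):
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        stats_r.append(dev[k] / sd)
        m = len(sub)
        p = 1.0 - alpha / (2.0 * m)
        t = stats.t.ppf(p, m - 2)
        lams.append((m - 1) * t / math.sqrt((m - 2 + t * t) * m))
        removed.append(remaining[k])
        remaining = np.delete(remaining, k)
    mask = np.zeros(n, dtype=bool)
    flag_up_to = 0
    for i, (r, lam) in enumerate(zip(stats_r, lams), start=1):
        if r > lam:
            flag_up_to = i
    mask[removed[:flag_up_to]] = True
    return mask


def shift_statistics(pairs_by_type: dict, random_coil: RandomCoilTable,
                     sequence, alpha: float = 0.05,
                     esd_min_points: int = 10) -> EvaluationReport:
    """Per-type RMSD, Pearson r and slope with ESD outlier removal.

    ``pairs_by_type`` maps atom type -> (residues, delta_pred, delta_exp)
    aligned arrays.  RMSD is computed on raw shifts; r and the slope on
    secondary shifts (sequence-corrected random-coil values subtracted
    from both predicted and experimental shifts, which isolates the
    structural contribution and cancels exactly in the RMSD).
    """
    report = EvaluationReport()
    for at, (residues, pred, exp) in pairs_by_type.items():
        residues = np.asarray(residues, dtype=int)
        pred = np.asarray(pred, dtype=float)
        exp = np.asarray(exp, dtype=float)
        resid = exp - pred
        if len(resid) >= esd_min_points:
            mask = esd_outlier_filter(resid, alpha=alpha)
        else:
            mask = np.zeros(len(resid), dtype=bool)
        keep = ~mask
        rc = np.array([random_coil.lookup(sequence, r, at) for r in residues])
        sec_pred = (pred - rc)[keep]
        sec_exp = (exp - rc)[keep]
        report.rmsd[at] = float(np.sqrt(np.mean(resid[keep] ** 2)))
        if len(sec_exp) >= 3 and sec_pred.std() > 0 and sec_exp.std() > 0:
            report.pearson_r[at] = float(np.corrcoef(sec_pred, sec_exp)[0, 1])
            report.slope[at], _, _ = ls_slope_offset(sec_exp, sec_pred)
        else:
            report.pearson_r[at] = float("nan")
            report.slope[at] = float("nan")
        report.n_used[at] = int(keep.sum())
        report.outliers[at] = mask
    return report


def residue_epsilon(deviations: dict, s: dict) -> dict:
    """Unit-less per-residue chemical-shift error.

    ``deviations`` maps residue_index -> {atom_type: delta_exp - delta_pred}.
    epsilon_i is the root-mean-square of the s-normalized deviations over
    the atom types available for residue i; a deviation of exactly s_j in
    every type gives epsilon = 1.
    """
    out = {}
    for res, devs in deviations.items():
        if not devs:
            continue
        terms = []
        for at, d in devs.items():
            if at not in s or s[at] <= 0:
                raise ShiftEnergyError(f"missing/invalid scale for atom type {at}")
            terms.append((d / s[at]) ** 2)
        out[res] = float(math.sqrt(sum(terms) / len(terms)))
    return out


def amino_acid_offsets(per_protein_pairs: list) -> dict:
    """Amino-acid-type shift offsets from one or more proteins.

    Each element of ``per_protein_pairs`` is a list of
    (residue_type, atom_type, delta_pred, delta_exp) tuples for one
    protein.  The offset for a (residue_type, atom_type) cell is the mean
    over proteins of that protein's mean deviation (delta_exp -
    delta_pred) for the cell; cells with no observation get 0.
    """
    per_protein_means = {}
    for pairs in per_protein_pairs:
        sums = {}
        for res_type, at, pred, exp in pairs:
            key = (res_type, at)
            tot, cnt = sums.get(key, (0.0, 0))
            sums[key] = (tot + (exp - pred), cnt + 1)
        for key, (tot, cnt) in sums.items():
            per_protein_means.setdefault(key, []).append(tot / cnt)
    return {key: float(np.mean(v)) for key, v in per_protein_means.items()}


def apply_offsets(pairs, offsets: dict):
    """Add the amino-acid-type offset to each predicted shift."""
    out = []
    for res_type, at, pred, exp in pairs:
        out.append((res_type, at, pred + offsets.get((res_type, at), 0.0), exp))
    return out


def ensemble_average_shieldings(ensemble: list) -> dict:
    """Arithmetic mean of per-atom shielding maps over an ensemble."""
    if not ensemble:
        raise ShiftEnergyError("empty ensemble")
    keys = set(ensemble[0])
    for m in ensemble[1:]:
        if set(m) != keys:
            raise ShiftEnergyError("shielding maps do not share keys")
    return {k: float(np.mean([m[k] for m in ensemble])) for k in keys}


def calibrate_per_protein(sigma_map: dict, pairs):
    """Per-type linear calibration of shieldings against experiment.

    Returns (rmsd_by_type, r_by_type, overall_rmsd) where predictions are
    a_j*sigma + b_j with (a_j, b_j) fitted per atom type on this protein.
    """
    ds = ShiftDataset.from_pairs(sigma_map, pairs)
    rmsd, rvals = {}, {}
    sq, cnt = 0.0, 0
    for at, g in ds.data.items():
        if len(g["sigma"]) < 3:
            continue
        try:
            a, b, rss = ls_slope_offset(g["sigma"], g["delta"])
        except ShiftEnergyError:
            continue
        n = len(g["sigma"])
        rmsd[at] = float(math.sqrt(rss / n))
        pred = a * g["sigma"] + b
        if pred.std() > 0 and g["delta"].std() > 0:
            rvals[at] = float(np.corrcoef(pred, g["delta"])[0, 1])
        sq += rss
        cnt += n
    overall = float(math.sqrt(sq / cnt)) if cnt else float("nan")
    return rmsd, rvals, overall
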