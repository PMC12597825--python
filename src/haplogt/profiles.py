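"""Dataset-specific WGS profiles: insert size, sequencing errors, read depth.

Three models are fitted from read alignments to a background region and are
reused at genotyping time:

* **Insert size** — negative binomial, fitted by the method of moments after
  discarding outliers above three times the 99th percentile.
* **Error profile** — per-operation rates (match, mismatch, insertion,
  deletion) giving a fast alignment likelihood, plus a beta-binomial model
  of edit distance given read length used to separate true from off-target
  alignments.
* **Read depth** — per-GC-content negative binomial of haploid window depth,
  obtained by local polynomial regression of window depth mean and variance
  on GC followed by moment matching.

NB parameterization throughout: NB(n, psi) with mean n(1-psi)/psi — the
``scipy.stats.nbinom`` convention.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

RATE_FLOOR = 1e-6
POISSON_PSI = 0.999  # fallback "almost Poisson" NB when variance <= mean


def nb_moment_fit(mean: float, var: float) -> tuple[float, float]:
    """(n, psi) matching the given mean and variance.

    Underdispersed samples (var <= mean) cannot be matched by an NB; they
    fall back to a near-Poisson NB with psi fixed at 0.999.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if var <= mean:
        psi = POISSON_PSI
        n = mean * psi / (1.0 - psi)
        return n, psi
    psi = mean / var
    n = mean * mean / (var - mean)
    return n, psi


def _thin_psi(psi: float, rho: float) -> float:
    """NB success probability after binomial thinning with keep-rate rho."""
    return psi / (psi + rho * (1.0 - psi))


@dataclass
class InsertSizeModel:
    """Negative-binomial insert-size distribution with outlier bounds."""

    n: float
    psi: float
    max_insert: int
    ci999: tuple[int, int]

    @property
    def mean(self) -> float:
        return self.n * (1.0 - self.psi) / self.psi

    @property
    def mode_log_pmf(self) -> float:
        """Log-pmf at the distribution mode (best achievable insert term)."""
        if self.n > 1.0:
            mode = math.floor((self.n - 1.0) * (1.0 - self.psi) / self.psi)
        else:
            mode = 0
        return float(stats.nbinom.logpmf(mode, self.n, self.psi))

    def log_pmf(self, insert: int) -> float:
        if insert < 0:
            return -math.inf
        return float(stats.nbinom.logpmf(insert, self.n, self.psi))

    def in_ci(self, insert: int) -> bool:
        lo, hi = self.ci999
        return lo <= insert <= hi


def fit_insert_size(insert_sizes, min_pairs: int = 100) -> InsertSizeModel:
    """Fit the insert-size NB by the method of moments.

    The maximum allowed insert is three times the 99th percentile of the raw
    sizes; larger values are discarded before fitting.  The stored 99.9%
    central interval of the fitted NB gates read pairs used by the error and
    depth fits.
    """
    sizes = np.asarray(list(insert_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("no insert sizes provided")
    if sizes.size < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} read pairs to fit insert sizes, "
            f"got {sizes.size}")
    max_insert = int(3 * np.percentile(sizes, 99))
    kept = sizes[sizes <= max_insert]
    mean = float(kept.mean())
    var = float(kept.var(ddof=1))
    if var <= mean:
        warnings.warn("insert sizes underdispersed; using near-Poisson NB")
    n, psi = nb_moment_fit(mean, var)
    lo = int(stats.nbinom.ppf(0.0005, n, psi))
    hi = int(stats.nbinom.ppf(0.9995, n, psi))
    return InsertSizeModel(n=n, psi=psi, max_insert=max_insert, ci999=(lo, hi))


@dataclass
class ErrorProfile:
    """Operation rates and beta-binomial edit-distance model.

    ``p_match``, ``p_mismatch`` and ``p_ins`` are rates per consumed read
    base; ``p_del`` is a rate per aligned reference base, so the alignment
    likelihood keeps its product form P_M^m * P_X^x * P_I^i * P_D^d.
    """

    bb_alpha: float
    bb_beta: float
    p_match: float
    p_mismatch: float
    p_ins: float
    p_del: float

    def __post_init__(self) -> None:
        for name in ("bb_alpha", "bb_beta", "p_match", "p_mismatch",
                     "p_ins", "p_del"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bb_mean_rate(self) -> float:
        return self.bb_alpha / (self.bb_alpha + self.bb_beta)

    def alignment_log_prob(self, matches: int, mismatches: int,
                           ins: int, dels: int) -> float:
        """Log alignment likelihood: sum of op counts times log rates.

        Only comparable between alignments of the same read.
        """
        if min(matches, mismatches, ins, dels) < 0:
            raise ValueError("operation counts must be non-negative")
        return (matches * math.log(self.p_match)
                + mismatches * math.log(self.p_mismatch)
                + ins * math.log(self.p_ins)
                + dels * math.log(self.p_del))

    def bb_pvalue(self, edit_distance: int, read_len: int) -> float:
        """Upper tail P(K >= k) of the beta-binomial at this read length."""
        if not 0 <= edit_distance <= read_len:
            raise ValueError("edit distance must be within [0, read_len]")
        if edit_distance == 0:
            return 1.0
        return float(stats.betabinom.sf(edit_distance - 1, read_len,
                                        self.bb_alpha, self.bb_beta))


def _fit_bb(edit_distances: np.ndarray, read_lens: np.ndarray,
            tol: float = 1e-8) -> tuple[float, float]:
    """Beta-binomial MLE of (alpha, beta) from per-read edit distances."""
    k = edit_distances.astype(float)
    n = read_lens.astype(float)
    rate = max(float(k.sum() / n.sum()), RATE_FLOOR)
    # method-of-moments start: match mean rate, modest overdispersion
    a0 = max(rate * 50.0, 1e-3)
    b0 = max((1.0 - rate) * 50.0, 1e-3)

    def nll(log_ab):
        a, b = np.exp(log_ab)
        return -np.sum(stats.betabinom.logpmf(k, n, a, b))

    res = optimize.minimize(nll, x0=np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": tol, "fatol": tol,
                                     "maxiter": 2000})
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_error_profile(alignments) -> ErrorProfile:
    """Fit operation rates and the beta-binomial edit-distance model.

    ``alignments`` is an iterable of (read_len, matches, mismatches,
    insertions, deletions) tuples from filtered background alignments.
    Rates are pooled counts over pooled denominators (read bases consumed
    for M/X/I; aligned reference bases for D), floored at 1e-6.
    """
    recs = [tuple(a) for a in alignments]
    if not recs:
        raise ValueError("no alignments provided")
    arr = np.asarray(recs, dtype=float)
    read_len, m, x, i, d = arr.T
    read_bases = (m + x + i).sum()
    ref_bases = (m + x + d).sum()
    if read_bases <= 0 or ref_bases <= 0:
        raise ValueError("alignments contain no aligned bases")
    p_m = max(m.sum() / read_bases, RATE_FLOOR)
    p_x = max(x.sum() / read_bases, RATE_FLOOR)
    p_i = max(i.sum() / read_bases, RATE_FLOOR)
    # renormalize read-consuming rates so they stay a probability simplex
    s = p_m + p_x + p_i
    p_m, p_x, p_i = p_m / s, p_x / s, p_i / s
    p_d = min(max(d.sum() / ref_bases, RATE_FLOOR), 1.0 - RATE_FLOOR)
    edit = x + i + d
    alpha, beta = _fit_bb(edit, read_len)
    return ErrorProfile(bb_alpha=alpha, bb_beta=beta, p_match=p_m,
                        p_mismatch=p_x, p_ins=p_i, p_del=p_d)


@dataclass
class DepthModel:
    """GC-stratified negative binomial of haploid window read depth.

    ``table`` maps integer GC percentages to (n, psi).  ``subsample_rate``
    records the thinning applied to the reads the model was fitted on; use
    :meth:`at_rate` to transport the model to a different rate via binomial
    thinning of the NB.
    """

    window_size: int
    table: dict[int, tuple[float, float]]
    subsample_rate: float = 1.0

    def params(self, gc: float) -> tuple[float, float]:
        """(n, psi) for a GC fraction or percentage, nearest fitted bin."""
        pct = int(round(gc * 100)) if gc <= 1.0 else int(round(gc))
        if pct in self.table:
            return self.table[pct]
        keys = np.fromiter(self.table.keys(), dtype=int)
        nearest = int(keys[np.argmin(np.abs(keys - pct))])
        return self.table[nearest]

    def mean_depth(self, gc: float) -> float:
        n, psi = self.params(gc)
        return n * (1.0 - psi) / psi

    def at_rate(self, rho: float) -> "DepthModel":
        """Model of depth thinned by an additional factor rho."""
        if not 0 < rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        table = {gc: (n, _thin_psi(psi, rho)) for gc, (n, psi) in self.table.items()}
        return DepthModel(self.window_size, table, self.subsample_rate * rho)


def _local_poly_smooth(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                       span: float) -> np.ndarray:
    """Tricube-weighted local quadratic regression evaluated on ``grid``."""
    n = x.size
    m = max(int(math.ceil(span * n)), 8)
    out = np.empty(grid.size)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for j, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argsort(d, kind="stable")[:m]
        dmax = d[idx].max()
        if dmax == 0:
            out[j] = ys[idx].mean()
            continue
        wgt = (1 - (d[idx] / dmax) ** 3) ** 3
        wgt = np.maximum(wgt, 1e-12)
        X = np.vander(xs[idx] - g, 3)  # quadratic basis
        W = np.sqrt(wgt)
        beta, *_ = np.linalg.lstsq(X * W[:, None], ys[idx] * W, rcond=None)
        out[j] = beta[-1]  # intercept = value at g
    return out


def fit_depth_model(window_records, window_size: int,
                    subsample_rate: float = 1.0,
                    span: float = 0.3, min_windows: int = 200,
                    unique_frac_min: float = 0.9) -> DepthModel:
    """Fit the per-GC depth NB from background window statistics.

    ``window_records`` is an iterable of (depth, gc, unique_kmer_frac)
    tuples, with depth the count of first-mate primary alignments assigned
    to the window (first mates only, which preserves window independence;
    for a diploid background this count matches, in expectation, the
    per-haplotype read-*end* depth the genotype likelihood evaluates for
    paired reads — single-end data should thin the model with
    ``at_rate(0.5)``).  Only windows with at least 90% unique k-mers enter
    the fit.  Depth mean and variance are smoothed along GC with a tricube
    local quadratic regression (predictions clamped to the observed GC
    range) and converted to NB parameters by moment matching.
    """
    recs = np.asarray([tuple(r) for r in window_records], dtype=float)
    if recs.size == 0:
        raise ValueError("no windows provided")
    depth, gc, uniq = recs.T
    keep = uniq >= unique_frac_min
    depth, gc = depth[keep], gc[keep]
    if depth.size < min_windows:
        raise ValueError(
            f"need at least {min_windows} windows with unique k-mer "
            f"fraction >= {unique_frac_min}, got {depth.size}")
    gc_pct = gc * 100.0 if gc.max() <= 1.0 else gc
    lo, hi = int(np.floor(gc_pct.min())), int(np.ceil(gc_pct.max()))
    grid = np.arange(0, 101, dtype=float)
    # clamp outside the observed range: no extrapolation beyond support
    eval_at = np.clip(grid, lo, hi)
    mean_s = _local_poly_smooth(gc_pct, depth, eval_at, span)
    var_s = _local_poly_smooth(gc_pct, (depth - np.interp(gc_pct, eval_at, mean_s)) ** 2,
                               eval_at, span)
    overall_mean = float(depth.mean())
    table: dict[int, tuple[float, float]] = {}
    for g, mu, va in zip(grid.astype(int), mean_s, var_s):
        mu = max(mu, 0.01 * overall_mean, 1e-3)
        table[g] = nb_moment_fit(mu, max(va, 0.0))
    return DepthModel(window_size=window_size, table=table,
                      subsample_rate=subsample_rate)


@dataclass
class WgsProfile:
    """Bundle of the three fitted dataset profiles."""

    insert: InsertSizeModel | None
    error: ErrorProfile
    depth: DepthModel

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "insert": asdict(self.insert) if self.insert else None,
            "error": asdict(self.error),
            "depth": {
                "window_size": self.depth.window_size,
                "subsample_rate": self.depth.subsample_rate,
                "table": {str(k): list(v) for k, v in self.depth.table.items()},
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "WgsProfile":
        doc = json.loads(text)
        ins = doc["insert"]
        insert = None
        if ins is not None:
            ins["ci999"] = tuple(ins["ci999"])
            insert = InsertSizeModel(**ins)
        error = ErrorProfile(**doc["error"])
        dep = doc["depth"]
        depth = DepthModel(
            window_size=dep["window_size"],
            subsample_rate=dep["subsample_rate"],
            table={int(k): (v[0], v[1]) for k, v in dep["table"].items()},
        )
        return cls(insert=insert, error=error, depth=depth)
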