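"""Accuracy and robustness evaluation.

* **Bland-Altman agreement**, per coordinate component: the error is the
  proposed-minus-gold difference; fixed bias is tested with a one-sample
  t-test of the mean difference against zero, proportional bias with an OLS
  regression of the difference on the pairwise mean (t-test of zero slope).
  Limits of agreement are mean +/- 1.96 SD.  Parametric tests are
  appropriate at the large sample sizes these pipelines produce.
* **Resultant error**: the Euclidean norm of the 3D error vector; summarised
  by the mean and the empirical 95th/99th percentiles (linear interpolation
  between order statistics).
* **Robustness Monte Carlo**: repeatedly perturb the digitized coordinates
  of a reconstructed point inside the reprojection of a small sphere
  (default diameter 12 mm, half the 24 mm marker) centred on it,
  re-triangulate, and record the displacement — stratified by the number of
  contributing cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .geometry import CameraModel, project
from .reconstruction import ReconstructedPoint


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanComponentResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_fixed: float
    slope: float
    p_slope: float
    intercept: float
    fixed_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    n: int
    degenerate: bool = False


def _component_result(diff: np.ndarray, mean_pair: np.ndarray, alpha: float = 0.05) -> BlandAltmanComponentResult:
    n = len(diff)
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    degenerate = sd_diff == 0.0
    if degenerate:
        t_stat, p_fixed = np.nan, np.nan
        ci = (mean_diff, mean_diff)
    else:
        t_stat, p_fixed = stats.ttest_1samp(diff, 0.0)
        half = stats.t.ppf(1 - alpha / 2, n - 1) * sd_diff / np.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
    if degenerate or np.std(mean_pair) == 0.0:
        slope, p_slope, intercept, sci = 0.0, np.nan, mean_diff, (0.0, 0.0)
    else:
        reg = stats.linregress(mean_pair, diff)
        slope, intercept, p_slope = reg.slope, reg.intercept, reg.pvalue
        half = stats.t.ppf(1 - alpha / 2, n - 2) * reg.stderr
        sci = (slope - half, slope + half)
    return BlandAltmanComponentResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        t_stat=float(t_stat),
        p_fixed=float(p_fixed),
        slope=float(slope),
        p_slope=float(p_slope),
        intercept=float(intercept),
        fixed_ci=(float(ci[0]), float(ci[1])),
        slope_ci=(float(sci[0]), float(sci[1])),
        n=n,
        degenerate=degenerate,
    )


def bland_altman(
    proposed: np.ndarray, gold: np.ndarray
) -> dict[str, BlandAltmanComponentResult]:
    """Per-component (x, y, z) agreement between two paired 3D measurements."""
    P = np.asarray(proposed, dtype=float).reshape(-1, 3)
    G = np.asarray(gold, dtype=float).reshape(-1, 3)
    if P.shape != G.shape:
        raise ValueError("proposed and gold must be paired and equal length")
    if len(P) < 3:
        raise ValueError("need at least 3 paired samples")
    out = {}
    for i, comp in enumerate("xyz"):
        diff = P[:, i] - G[:, i]
        mean_pair = (P[:, i] + G[:, i]) / 2.0
        out[comp] = _component_result(diff, mean_pair)
    return out


# ---------------------------------------------------------------------------
# resultant error
# ---------------------------------------------------------------------------

@dataclass
class ResultantErrorStats:
    mean: float
    p95: float
    p99: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n: int


def resultant_error_stats(error_vectors: np.ndarray, *, bins: int = 50) -> ResultantErrorStats:
    """Norms of 3D error vectors: mean, 95th/99th percentile, histogram."""
    E = np.asarray(error_vectors, dtype=float).reshape(-1, 3)
    if len(E) == 0:
        raise ValueError("no error vectors")
    norms = np.linalg.norm(E, axis=1)
    counts, edges = np.histogram(norms, bins=bins)
    return ResultantErrorStats(
        mean=float(np.mean(norms)),
        p95=float(np.percentile(norms, 95)),  # linear interpolation convention
        p99=float(np.percentile(norms, 99)),
        hist_counts=counts,
        hist_edges=edges,
        n=len(norms),
    )


# ---------------------------------------------------------------------------
# robustness Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class RobustnessConfig:
    noise_sphere_diameter_mm: float = 12.0
    iterations: int = 1_000_000
    seed: int = 0
    noise_mode: str = "all"  # perturb all contributing cameras, or "one"

    def __post_init__(self) -> None:
        if self.noise_sphere_diameter_mm < 0:
            raise ValueError("noise sphere diameter must be >= 0")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")
        if self.noise_mode not in ("all", "one"):
            raise ValueError("noise_mode must be 'all' or 'one'")


@dataclass
class RobustnessResult:
    mean_mm: float
    max_mm: float
    iterations: int
    n_points: int


def _disc_radius_px(cam: CameraModel, point: np.ndarray, sphere_radius_mm: float) -> float:
    """Radius in px of the reprojection of a sphere centred at ``point``."""
    view = point - cam.center
    view /= np.linalg.norm(view)
    ref = np.array([0.0, 0.0, 1.0]) if abs(view[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(view, ref)
    perp /= np.linalg.norm(perp)
    p0 = np.asarray(project(cam, point))
    p1 = np.asarray(project(cam, point + sphere_radius_mm * perp))
    return float(np.linalg.norm(p1 - p0))


def robustness_mc(
    points: Sequence[ReconstructedPoint],
    cameras: Mapping[str, CameraModel],
    cfg: RobustnessConfig | None = None,
) -> dict[int, RobustnessResult]:
    """Perturbation Monte Carlo, stratified by contributing-camera count.

    Each iteration samples a point uniformly within its stratum, perturbs the
    stored digitized coordinates of its contributing cameras by a uniform
    draw over the reprojected noise disc, re-triangulates, and records the
    displacement from the unperturbed reconstruction.
    """
    cfg = cfg or RobustnessConfig()
    for p in points:
        if not p.observations:
            raise ValueError("points must retain their digitized coordinates")
        for cid in p.cameras_used:
            if cid not in cameras:
                raise KeyError(f"unknown camera {cid!r}")

    rng = np.random.default_rng(cfg.seed)
    radius_mm = cfg.noise_sphere_diameter_mm / 2.0

    # camera back-projection caches
    Minv = {cid: np.linalg.inv(cameras[cid].M) for cid in cameras}
    centers = {cid: cameras[cid].center for cid in cameras}
    signs = {cid: cameras[cid]._depth_sign for cid in cameras}

    strata: dict[int, list[ReconstructedPoint]] = {}
    for p in points:
        strata.setdefault(len(p.cameras_used), []).append(p)

    out: dict[int, RobustnessResult] = {}
    for k in sorted(strata):
        pts = strata[k]
        # per-point precomputation: pixel, disc radius, ray origin per camera
        pre = []
        for p in pts:
            cams = sorted(p.cameras_used)
            uv = np.array([p.observations[c] for c in cams])
            radii = np.array(
                [
                    _disc_radius_px(cameras[c], p.position, radius_mm)
                    if radius_mm > 0
                    else 0.0
                    for c in cams
                ]
            )
            Mi = np.stack([Minv[c] for c in cams])
            O = np.stack([centers[c] for c in cams])
            sg = np.array([signs[c] for c in cams])
            # baseline point re-triangulated from the stored pixels so the
            # recorded displacement isolates the injected noise
            base = _triangulate_batch(uv[None, :, :], Mi, O, sg)[0]
            pre.append((uv, radii, Mi, O, sg, base))

        counts = rng.multinomial(cfg.iterations, np.full(len(pts), 1.0 / len(pts)))
        total, running_max, n_done = 0.0, 0.0, 0
        for (uv, radii, Mi, O, sg, base), m in zip(pre, counts):
            if m == 0:
                continue
            r = radii[None, :] * np.sqrt(rng.uniform(size=(m, k)))
            th = rng.uniform(0.0, 2 * np.pi, size=(m, k))
            noise = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
            if cfg.noise_mode == "one":
                keep = rng.integers(0, k, size=m)
                mask = np.zeros((m, k, 1))
                mask[np.arange(m), keep] = 1.0
                noise = noise * mask
            puv = uv[None, :, :] + noise
            X = _triangulate_batch(puv, Mi, O, sg)
            d = np.linalg.norm(X - base[None, :], axis=1)
            total += float(d.sum())
            running_max = max(running_max, float(d.max()))
            n_done += m
        out[k] = RobustnessResult(
            mean_mm=total / n_done, max_mm=running_max, iterations=n_done,
            n_points=len(pts),
        )
    return out


def _triangulate_batch(
    uv: np.ndarray, Minv: np.ndarray, origins: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Vectorised least-squares ray intersection.

    ``uv``: (n, k, 2) pixels; ``Minv``: (k, 3, 3); ``origins``: (k, 3);
    ``signs``: (k,).  Returns (n, 3) points.
    """
    n, k, _ = uv.shape
    xh = np.concatenate([uv, np.ones((n, k, 1))], axis=-1)
    d = np.einsum("kij,nkj->nki", Minv, xh) * signs[None, :, None]
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    eye = np.eye(3)[None, None, :, :]
    proj = eye - d[..., :, None] * d[..., None, :]
    A = proj.sum(axis=1)
    b = np.einsum("nkij,kj->ni", proj, origins)
    return np.linalg.solve(A, b[..., None])[..., 0]


# ---------------------------------------------------------------------------
# plotting (optional)
# ---------------------------------------------------------------------------

def plot_bland_altman(proposed, gold, path) -> None:
    """Three-panel Bland-Altman figure (difference vs mean per component)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(proposed, gold)
    P = np.asarray(proposed, dtype=float)
    G = np.asarray(gold, dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for i, comp in enumerate("xyz"):
        ax = axes[i]
        mean_pair = (P[:, i] + G[:, i]) / 2.0
        diff = P[:, i] - G[:, i]
        r = res[comp]
        ax.scatter(mean_pair, diff, s=2, alpha=0.3)
        ax.axhline(r.mean_diff, color="k")
        ax.axhline(r.loa_low, color="k", linestyle="--")
        ax.axhline(r.loa_high, color="k", linestyle="--")
        ax.set_title(f"{comp}: bias {r.mean_diff:.3f} mm")
        ax.set_xlabel("mean of methods (mm)")
        ax.set_ylabel("difference (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_histogram(error_vectors, path, *, bins: int = 50) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats_ = resultant_error_stats(error_vectors, bins=bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (stats_.hist_edges[:-1] + stats_.hist_edges[1:]) / 2.0
    ax.bar(centers, stats_.hist_counts, width=np.diff(stats_.hist_edges))
    ax.axvline(stats_.mean, color="k", label=f"mean {stats_.mean:.2f} mm")
    ax.set_xlabel("resultant error (mm)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
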