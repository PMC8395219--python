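"""Oligomer counting from single-particle intensity distributions.

A monomeric membrane-protein control (e.g. CD86) calibrates the
single-fluorophore intensity distribution; the intensity distribution of an
n-mer is the n-fold convolution of the monomer distribution. Observed
per-state intensity histograms are decomposed into mixtures over oligomer
sizes 1..n_max by non-negative least squares, with the basis corrected for
partial labeling: with per-subunit labeling probability p, a k-mer shows
the intensity of m labeled subunits with binomial weight, conditioned on
m ≥ 1 because fully dark particles are never detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class MonomerCalibration:
    """Fitted single-fluorophore intensity model for one dye.

    ``distribution`` is ``("lognormal", mu, sigma)`` with mean
    ``exp(mu + sigma²/2)``.
    """

    dye: str
    mean_intensity: float
    distribution: tuple

    def pdf(self, x: np.ndarray) -> np.ndarray:
        family, *params = self.distribution
        if family == "lognormal":
            mu, sigma = params
            return stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu))
        raise ValueError(f"unknown family {family!r}")


@dataclass
class OligomerDecomposition:
    """Mixture weights over oligomer sizes 1..n_max with fit residual."""

    weights: np.ndarray
    n_max: int
    residual: float


def calibrate_monomer(
    intensities: np.ndarray, dye: str = "dye1", family: str = "lognormal"
) -> MonomerCalibration:
    """Maximum-likelihood fit of the monomer intensity distribution.

    Lognormal MLE is closed-form on log intensities. Requires ≥200
    positive samples (the fitted mean must represent the control well).
    """
    x = np.asarray(intensities, float)
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    if len(x) < 200:
        raise ValueError(f"need >= 200 samples, got {len(x)}")
    if family != "lognormal":
        raise ValueError("only the lognormal family is implemented")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))
    mean = float(np.exp(mu + sigma**2 / 2)) if sigma > 0 else float(np.exp(mu))
    return MonomerCalibration(
        dye=dye, mean_intensity=mean, distribution=("lognormal", mu, sigma)
    )


# ----------------------------------------------------------------------
# n-mer intensity models on a fixed grid
# ----------------------------------------------------------------------
def intensity_grid(cal: MonomerCalibration, n_max: int = 8, n_bins: int = 256) -> np.ndarray:
    """Default analysis grid: 0 to n_max × monomer mean, ``n_bins`` points."""
    return np.linspace(0, n_max * cal.mean_intensity, n_bins)


def nmer_model(
    cal: MonomerCalibration, n: int, grid: np.ndarray | None = None, n_max: int = 8
) -> np.ndarray:
    """Intensity density of an n-mer on the grid (n-fold self-convolution).

    Computed by repeated discrete convolution of the monomer density;
    the result is renormalized on the grid (mass beyond the grid edge is
    truncated, negligible for n ≤ n_max with the default 0..8× range).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > n_max:
        raise ValueError(f"n={n} exceeds n_max={n_max}")
    if grid is None:
        grid = intensity_grid(cal, n_max)
    dx = grid[1] - grid[0]
    base = cal.pdf(grid)
    base = base / (base.sum() * dx)
    out = base.copy()
    for _ in range(n - 1):
        out = np.convolve(out, base)[: len(grid)] * dx
    s = out.sum() * dx
    if s > 0:
        out = out / s
    return out


def _visible_kmer_basis(
    cal: MonomerCalibration,
    k: int,
    labeling: float,
    grid: np.ndarray,
    n_max: int,
) -> np.ndarray:
    """Intensity density of a detected k-mer under partial labeling.

    Mixture over the number of labeled subunits m ~ Binomial(k, p),
    conditioned on m ≥ 1 (unlabeled particles are invisible).
    """
    if not (0 < labeling <= 1):
        raise ValueError("labeling probability must lie in (0, 1]")
    ms = np.arange(1, k + 1)
    w = stats.binom.pmf(ms, k, labeling)
    w = w / w.sum()
    out = np.zeros_like(grid)
    for m, wm in zip(ms, w):
        if wm > 0:
            out += wm * nmer_model(cal, int(m), grid=grid, n_max=n_max)
    return out


def decompose_histogram(
    counts: np.ndarray,
    bin_edges: np.ndarray,
    cal: MonomerCalibration,
    n_max: int = 8,
    labeling: float = 1.0,
) -> OligomerDecomposition:
    """NNLS decomposition of an intensity histogram into oligomer sizes.

    The observed histogram (``counts`` over ``bin_edges``) is regressed
    against the per-size visible-intensity basis; weights are constrained
    non-negative and normalized to 1. Residual is the relative L2 misfit of
    the normalized histogram.
    """
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("all-zero histogram")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    width = np.diff(bin_edges)
    target = counts / (counts * width).sum()  # density normalization
    basis = np.column_stack(
        [
            _visible_kmer_basis(cal, k, labeling, centers, n_max)
            for k in range(1, n_max + 1)
        ]
    )
    w, rnorm = optimize.nnls(basis, target)
    total = w.sum()
    if total <= 0:
        raise ValueError("decomposition failed: zero weight mass")
    weights = w / total
    residual = float(rnorm / np.linalg.norm(target))
    return OligomerDecomposition(weights=weights, n_max=n_max, residual=residual)


def difference_histogram(
    counts_before: np.ndarray,
    counts_after: np.ndarray,
    bin_edges_before: np.ndarray,
    bin_edges_after: np.ndarray,
    density_before: float = 1.0,
    density_after: float = 1.0,
) -> np.ndarray:
    """Signed per-bin difference (after − before) of intensity histograms.

    Both histograms are scaled to particle density before subtraction, so
    net loss of particles (endocytosis) appears as negative mass rather
    than being hidden by per-histogram normalization. Binning must match.
    """
    if len(counts_before) != len(counts_after) or not np.allclose(
        bin_edges_before, bin_edges_after
    ):
        raise ValueError("histogram binning mismatch")
    b = np.asarray(counts_before, float)
    a = np.asarray(counts_after, float)
    if b.sum() > 0:
        b = b / b.sum() * density_before
    if a.sum() > 0:
        a = a / a.sum() * density_after
    return a - b
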