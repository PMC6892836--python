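"""Exhaustive two-band index scans ("contour maps") for index discovery.

For every pair of wavelengths on a stepped grid the normalized-difference
index (Ra - Rb)/(Ra + Rb) is computed per plot and regressed against a
trait; the resulting matrix of coefficients of determination is the contour
map.  High-R2 "hot spots" are extracted as connected regions and their peak
wavelength pairs form the shortlist of single wavelengths from which new
two-band indices are constructed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectra import SpectraSet, WL_MIN


@dataclass
class ContourMap:
    """Symmetric R2 matrix over a stepped wavelength grid."""

    wavelengths: np.ndarray  # stepped grid, nm
    r2: np.ndarray  # (m, m), symmetric; masked cells are 0
    mask: np.ndarray  # True where the pair was excluded (diagonal band)
    trait: str
    scope: str
    step: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy (lambda1, lambda2, r2) rows for the upper triangle."""
        i, j = np.triu_indices(len(self.wavelengths), k=1)
        keep = ~self.mask[i, j]
        return pd.DataFrame(
            {
                "lambda1": self.wavelengths[i[keep]],
                "lambda2": self.wavelengths[j[keep]],
                "r2": self.r2[i[keep], j[keep]],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class HotspotRegion:
    peak: tuple[int, int]
    peak_r2: float
    n_cells: int


@dataclass
class HotspotSet:
    regions: list[HotspotRegion]
    threshold: float
    rule: str


def scan_pairs(
    spectra: SpectraSet,
    traits: pd.DataFrame,
    trait_name: str,
    step: int = 5,
    min_separation: int = 5,
    scope: str = "",
) -> ContourMap:
    """Scan all two-band normalized-difference indices against a trait.

    Pairs closer than ``min_separation`` nm are excluded (their index
    degenerates to a noise ratio).  Degenerate (zero-variance) index columns
    get R2 = 0 and are masked.  The scan is vectorized in blocks over the
    first wavelength.
    """
    if step < 1:
        raise ValueError("step must be >= 1 nm")
    if "plot_id" in traits.columns:
        traits = traits.set_index("plot_id")
    y = traits.loc[spectra.plot_ids, trait_name].to_numpy(dtype=float)
    yc = y - y.mean()
    sy = float(yc @ yc)
    if sy == 0:
        raise ValueError("trait has zero variance")

    grid = spectra.wavelengths.astype(int)[:: step]
    cols = (grid - WL_MIN).astype(int)
    R = spectra.values[:, cols]  # (n, m)
    m = len(grid)
    r2 = np.zeros((m, m))
    mask = np.zeros((m, m), dtype=bool)

    sep = np.abs(grid[:, None] - grid[None, :]) < min_separation
    mask |= sep

    block = 32
    for start in range(0, m, block):
        stop = min(start + block, m)
        ri = R[:, start:stop, None]  # (n, b, 1)
        rj = R[:, None, :]  # (n, 1, m)
        num = ri - rj
        den = ri + rj
        with np.errstate(divide="ignore", invalid="ignore"):
            idx = np.where(den != 0, num / den, 0.0)
        xc = idx - idx.mean(axis=0, keepdims=True)
        sx = np.einsum("nbm,nbm->bm", xc, xc)
        sxy = np.einsum("nbm,n->bm", xc, yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            blk = np.where(sx > 0, (sxy**2) / (sx * sy), 0.0)
        degenerate = sx <= 0
        r2[start:stop, :] = blk
        mask[start:stop, :] |= degenerate
    r2[mask] = 0.0
    np.fill_diagonal(r2, 0.0)
    return ContourMap(
        wavelengths=grid, r2=r2, mask=mask, trait=trait_name, scope=scope, step=step
    )


def extract_hotspots(
    cmap: ContourMap,
    threshold: float | None = None,
    quantile: float = 0.95,
) -> HotspotSet:
    """Connected high-R2 regions of the map (8-neighborhood) with peak pairs.

    The rule is either an absolute R2 ``threshold`` or, by default, the
    ``quantile`` of the unmasked map values.
    """
    valid = ~cmap.mask
    np.fill_diagonal(valid, False)
    vals = cmap.r2[np.triu(valid, k=1)]
    if threshold is None:
        if vals.size == 0:
            return HotspotSet(regions=[], threshold=np.nan, rule="empty map")
        threshold = float(np.quantile(vals, quantile))
        rule = f"top-{quantile:.2f}-quantile"
    else:
        rule = f"absolute>={threshold:g}"
    passing = (cmap.r2 >= threshold) & valid
    labels, n_lab = ndimage.label(passing, structure=np.ones((3, 3), dtype=int))
    regions = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        cell_r2 = cmap.r2[cells[:, 0], cells[:, 1]]
        k = int(np.argmax(cell_r2))
        i, j = cells[k]
        lo, hi = sorted((int(cmap.wavelengths[i]), int(cmap.wavelengths[j])))
        regions.append(
            HotspotRegion(peak=(lo, hi), peak_r2=float(cell_r2[k]), n_cells=len(cells))
        )
    # the map is symmetric: each region appears mirrored; deduplicate by peak
    unique: dict[tuple[int, int], HotspotRegion] = {}
    for reg in sorted(regions, key=lambda r: -r.peak_r2):
        unique.setdefault(reg.peak, reg)
    return HotspotSet(
        regions=sorted(unique.values(), key=lambda r: -r.peak_r2),
        threshold=float(threshold),
        rule=rule,
    )


def wavelength_shortlist(hotspots: HotspotSet) -> list[int]:
    """Sorted, deduplicated union of the peak-pair wavelengths."""
    if not hotspots.regions:
        raise ValueError("empty hotspot set")
    wl = {w for reg in hotspots.regions for w in reg.peak}
    return sorted(wl)
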