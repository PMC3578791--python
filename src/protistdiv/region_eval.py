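"""Calibration of partial-gene distances against full-gene distances.

Short barcode regions (e.g. the ~550 bp V4-V5 or ~160 bp V9 hypervariable
regions of the 18S rRNA gene) evolve at different rates than the gene as a
whole. To quantify how faithfully a region's pairwise distances track
full-gene distances, the matched pair distances are regressed (ordinary
least squares, free intercept) with the partial-region distance as the
response: a slope above 1 means the region overestimates full-gene
divergence by that factor, and the Pearson correlation R measures how tight
the relationship is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from protistdiv.distances import DistanceMatrix
from protistdiv.errors import DegenerateFitError, InputError

logger = logging.getLogger(__name__)

__all__ = ["RegionFit", "paired_region_fit", "write_pairs_tsv", "write_fit_json"]


@dataclass
class RegionFit:
    """OLS fit of partial-region on full-gene pairwise distances."""

    region_name: str
    m: float  # slope: partial distance per unit full-gene distance
    intercept: float
    R: float  # Pearson correlation
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise InputError(f"region fit needs >= 3 pairs, got {self.n_pairs}")
        if abs(self.R) > 1 + 1e-12:
            raise InputError(f"|R| must be <= 1, got {self.R}")


def paired_region_fit(
    full: DistanceMatrix, partial: DistanceMatrix, region_name: str = "region"
) -> RegionFit:
    """Regress partial-region distances on full-gene distances over all pairs.

    Both matrices must be over the same sequences (order may differ). Pairs
    with an undefined (nan, e.g. saturated) distance in either matrix are
    dropped and counted in the log.
    """
    if set(full.names) != set(partial.names):
        raise InputError("full and partial matrices must cover the same sequences")
    if full.n < 3:
        raise InputError(f"need >= 3 sequences, got {full.n}")
    order = [partial.names.index(name) for name in full.names]
    part_d = partial.d[np.ix_(order, order)]
    iu = np.triu_indices(full.n, k=1)
    x = full.d[iu]
    y = part_d[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "region %s: dropped %d/%d pairs with undefined distance",
            region_name, dropped, x.size,
        )
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InputError(f"only {x.size} defined pairs; need >= 3")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in full-gene distances")
    fit = stats.linregress(x, y)
    return RegionFit(
        region_name=region_name,
        m=float(fit.slope),
        intercept=float(fit.intercept),
        R=float(fit.rvalue),
        n_pairs=int(x.size),
    )


def write_pairs_tsv(full: DistanceMatrix, partial: DistanceMatrix, path) -> None:
    """TSV of (name1, name2, full_d, partial_d) for external plotting."""
    order = [partial.names.index(name) for name in full.names]
    part_d = partial.d[np.ix_(order, order)]
    with open(path, "w") as fh:
        fh.write("name1\tname2\tfull_d\tpartial_d\n")
        for i in range(full.n):
            for j in range(i + 1, full.n):
                fh.write(
                    f"{full.names[i]}\t{full.names[j]}\t"
                    f"{full.d[i, j]:.6f}\t{part_d[i, j]:.6f}\n"
                )


def write_fit_json(fits: list[RegionFit], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(f) for f in fits], fh, indent=2)
        fh.write("\n")
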