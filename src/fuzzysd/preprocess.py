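"""Bucket-intensity preprocessing chain.

The fixed order is: reference normalization (urinary creatinine in the
typical workflow) -> cube-root transform -> Pareto scaling, optionally
restricted first to a ppm window (e.g. the low-field aromatic region
6.71-9.43 ppm).  Cube-root compresses the right-skewed intensity
distribution while remaining defined at zero; Pareto scaling divides
centred features by the square root of their standard deviation, a
middle ground between unit-variance scaling and no scaling that is
standard in metabolomics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io import BucketTable, BucketTableError

_PPM_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*$")


@dataclass
class PreprocessPlan:
    reference_feature: str | None = None
    apply_cube_root: bool = True
    apply_pareto: bool = True
    ppm_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ppm_window is not None and not self.ppm_window[0] < self.ppm_window[1]:
            raise ValueError("ppm window must satisfy low < high")


def normalize_to_reference(table: BucketTable, reference_feature: str) -> BucketTable:
    """Divide every bucket row-wise by the reference bucket, then drop it.

    Normalising to creatinine corrects for urine dilution differences
    between donors; the reference bucket itself carries no information
    afterwards and is removed.
    """
    j = table.feature_index(reference_feature)
    ref = table.intensities[:, j]
    bad = np.where(ref <= 0)[0]
    if bad.size:
        raise BucketTableError(
            f"reference feature {reference_feature!r} non-positive in sample(s) "
            + ", ".join(table.sample_ids[i] for i in bad)
        )
    keep = [k for k in range(table.n_features) if k != j]
    matrix = table.intensities[:, keep] / ref[:, None]
    names = [table.feature_names[k] for k in keep]
    return table.with_intensities(matrix, feature_names=names)


def cube_root(table: BucketTable) -> BucketTable:
    return table.with_intensities(np.cbrt(table.intensities))


def pareto_scale(table: BucketTable) -> BucketTable:
    """Centre each feature and divide by sqrt of its (n-1) standard deviation."""
    if table.n_samples < 2:
        raise BucketTableError("Pareto scaling needs at least 2 samples")
    sd = table.intensities.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        raise BucketTableError(
            "constant feature(s): " + ", ".join(table.feature_names[k] for k in const)
        )
    scaled = (table.intensities - table.intensities.mean(axis=0)) / np.sqrt(sd)
    return table.with_intensities(scaled)


def parse_ppm_range(name: str) -> tuple[float, float]:
    """Parse a bucket name of the form ``"a-b"`` (hyphen or en-dash)."""
    m = _PPM_RE.match(name)
    if m is None:
        raise BucketTableError(f"feature name {name!r} is not a ppm range")
    return float(m.group(1)), float(m.group(2))


def select_ppm_region(table: BucketTable, low: float, high: float) -> BucketTable:
    """Keep buckets whose midpoint lies in [low, high] ppm.

    The midpoint, not the edges, decides membership so that buckets
    straddling a region boundary are assigned unambiguously.
    """
    keep = []
    for k, name in enumerate(table.feature_names):
        a, b = parse_ppm_range(name)
        if low <= (a + b) / 2.0 <= high:
            keep.append(k)
    if not keep:
        raise BucketTableError(f"no buckets with midpoint in [{low}, {high}] ppm")
    return table.with_intensities(
        table.intensities[:, keep], feature_names=[table.feature_names[k] for k in keep]
    )


def apply_chain(table: BucketTable, plan: PreprocessPlan) -> BucketTable:
    """Run the full chain once; refuses already-processed tables."""
    if table.processed:
        raise BucketTableError("table already preprocessed; chain is not idempotent")
    out = table
    if plan.ppm_window is not None:
        out = select_ppm_region(out, *plan.ppm_window)
    if plan.reference_feature is not None:
        out = normalize_to_reference(out, plan.reference_feature)
    if plan.apply_cube_root:
        out = cube_root(out)
    if plan.apply_pareto:
        out = pareto_scale(out)
    return out.with_intensities(out.intensities, processed=True)
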