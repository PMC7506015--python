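"""Beta/M transforms, sample-purity screening, region aggregation and QC.

All matrices are pandas DataFrames with probe (or region) ids on the
index and sample ids on the columns, matching the on-disk TSV layout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import RegionMap

__all__ = ["beta_to_m", "m_to_beta", "purity_screen", "aggregate_regions", "qc_filter"]

log = logging.getLogger(__name__)


def beta_to_m(beta: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)), with beta clipped to [eps, 1-eps].

    The clip keeps M finite at the boundaries; eps must lie in (0, 0.5).
    Values outside [0, 1] indicate corrupt input and raise.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    vals = beta.to_numpy(dtype=float)
    if np.isnan(vals).all():
        raise ValueError("beta matrix contains no data")
    with np.errstate(invalid="ignore"):
        bad = (vals < 0.0) | (vals > 1.0)
    if bad.any():
        raise ValueError(f"{bad.sum()} beta values outside [0, 1]")
    clipped = np.clip(vals, eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` on unclipped values."""
    vals = m.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-vals))
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def purity_screen(
    beta: pd.DataFrame,
    region_map: RegionMap,
    marker_region: str | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag samples whose marker-locus methylation looks somatic.

    The marker locus is essentially unmethylated in pure sperm and highly
    methylated in somatic DNA, so a sample fails when its mean beta
    across the marker CpGs exceeds ``threshold`` (default 0.5, the
    midpoint between the two signatures).

    Returns a per-sample report: ``sample, marker_mean_beta, verdict``.
    """
    marker = marker_region if marker_region is not None else region_map.marker_region
    if marker is None or marker not in region_map.regions:
        raise ValueError(f"marker region {marker!r} not present in the region map")
    probes = [p for p in region_map.probes(marker) if p in beta.index]
    if not probes:
        raise ValueError(f"no probes of marker region {marker!r} found in the matrix")
    means = beta.loc[probes].mean(axis=0)
    return pd.DataFrame(
        {
            "sample": means.index,
            "marker_mean_beta": means.to_numpy(),
            "verdict": np.where(means.to_numpy() > threshold, "fail", "pass"),
        }
    ).reset_index(drop=True)


def aggregate_regions(
    matrix: pd.DataFrame,
    region_map: RegionMap,
    include_marker: bool = False,
) -> pd.DataFrame:
    """Average probe-level values into region-level features, per sample.

    Unweighted mean over member CpGs. Regions whose probes are partially
    missing from the matrix are aggregated over the present probes and
    logged; a region with no probes present raises.
    """
    rows = {}
    for rid, probes in region_map.regions.items():
        if not include_marker and rid == region_map.marker_region:
            continue
        if len(probes) == 0:
            raise ValueError(f"region {rid!r} is empty")
        present = [p for p in probes if p in matrix.index]
        if not present:
            raise ValueError(f"region {rid!r} has no probes in the matrix")
        if len(present) < len(probes):
            log.warning("region %s: %d/%d probes missing", rid, len(probes) - len(present), len(probes))
        rows[rid] = matrix.loc[present].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "region_id"
    out.columns = matrix.columns
    return out


def qc_filter(matrix: pd.DataFrame, max_missing_fraction: float = 0.1):
    """Drop probes with too many missing values.

    Returns ``(filtered, report)`` where report counts kept/dropped
    probes and lists the dropped ids.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    missing_frac = matrix.isna().mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    dropped = matrix.index[~keep].tolist()
    report = {
        "n_probes_in": int(matrix.shape[0]),
        "n_probes_kept": int(keep.sum()),
        "n_probes_dropped": len(dropped),
        "dropped_probes": dropped,
    }
    return matrix.loc[keep], report
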