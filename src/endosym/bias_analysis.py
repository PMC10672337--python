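"""Group-level codon-usage-bias analyses.

Three classical diagnostics over a set of gene profiles (a genetic group or
a single genome): the PR2 bias plot summary (quadrant occupancy around
(0.5, 0.5) plus a 95% confidence ellipse of the point cloud), the
neutrality plot (OLS regression of GC12 on GC3 — a slope near 1 indicates
mutation pressure, near 0 selection/constraint), and the ENC plot (observed
ENC against the no-selection expectation at the gene's GC3s, with genes
falling below the curve by more than a margin flagged as selection-shaped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_stats import GeneCodonProfile, enc_expected


@dataclass
class Pr2Summary:
    group_id: str
    points: np.ndarray          # (n, 2) defined (x, y) coordinates
    mean_point: tuple[float, float]
    quadrant_counts: tuple[int, int, int, int]  # (x≥.5,y≥.5), (x<.5,y≥.5), (x<.5,y<.5), (x≥.5,y<.5)
    ellipse_center: tuple[float, float]
    ellipse_axes: tuple[float, float]   # semi-axis lengths, major first
    ellipse_angle_deg: float
    n_genes: int
    n_excluded: int


@dataclass(frozen=True)
class NeutralityFit:
    group_id: str
    slope: float
    intercept: float
    r_squared: float
    n_genes: int


@dataclass
class EncPlotSummary:
    group_id: str
    table: pd.DataFrame  # locus_id, genome_id, gc3s, enc, enc_exp, deviation, below
    fraction_below: float
    margin: float


def _pr2_points(profiles: list[GeneCodonProfile]) -> tuple[np.ndarray, int]:
    pts, excluded = [], 0
    for p in profiles:
        x = p.g3 / (p.g3 + p.c3) if (p.g3 + p.c3) else math.nan
        y = p.a3 / (p.a3 + p.t3) if (p.a3 + p.t3) else math.nan
        if math.isnan(x) or math.isnan(y):
            excluded += 1
        else:
            pts.append((x, y))
    return np.array(pts, dtype=float).reshape(-1, 2), excluded


def pr2_summary(profiles: list[GeneCodonProfile], group_id: str) -> Pr2Summary:
    """PR2 scatter summary; boundary points (exactly 0.5) go to the
    upper/right quadrant.  The ellipse is the 95% chi-square contour of the
    sample covariance (degenerate clouds give zero-length axes)."""
    pts, excluded = _pr2_points(profiles)
    if len(pts) < 3:
        raise ValueError("need at least 3 genes with defined PR2 coordinates")
    x, y = pts[:, 0], pts[:, 1]
    right, upper = x >= 0.5, y >= 0.5
    quad = (int((right & upper).sum()), int((~right & upper).sum()),
            int((~right & ~upper).sum()), int((right & ~upper).sum()))
    center = (float(x.mean()), float(y.mean()))
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = stats.chi2.ppf(0.95, df=2)
    axes = np.sqrt(evals * scale)[::-1]           # major first
    major = evecs[:, -1]
    angle = math.degrees(math.atan2(major[1], major[0]))
    return Pr2Summary(group_id=group_id, points=pts, mean_point=center,
                      quadrant_counts=quad, ellipse_center=center,
                      ellipse_axes=(float(axes[0]), float(axes[1])),
                      ellipse_angle_deg=angle, n_genes=len(pts), n_excluded=excluded)


def neutrality_fit(profiles: list[GeneCodonProfile], group_id: str) -> NeutralityFit:
    """OLS of GC12 (response) on GC3 (predictor); R² is the squared Pearson
    correlation.  Raises on a constant GC3 (degenerate regression)."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 genes")
    gc3 = np.array([p.gc3 for p in profiles])
    gc12 = np.array([p.gc12 for p in profiles])
    if np.ptp(gc3) == 0:
        raise ValueError("degenerate regression: GC3 is constant")
    if np.ptp(gc12) == 0:  # constant response: flat line, no explained variance
        return NeutralityFit(group_id=group_id, slope=0.0,
                             intercept=float(gc12[0]), r_squared=0.0,
                             n_genes=len(profiles))
    fit = stats.linregress(gc3, gc12)
    return NeutralityFit(group_id=group_id, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2, n_genes=len(profiles))


def enc_plot(profiles: list[GeneCodonProfile], group_id: str,
             margin: float = 0.05) -> EncPlotSummary:
    """Per-gene deviation from the expected-ENC curve,
    (ENC_exp − ENC)/ENC_exp, and the fraction of genes beneath the curve by
    more than ``margin``."""
    rows = []
    for p in profiles:
        if math.isnan(p.enc) or math.isnan(p.gc3s):
            continue
        exp = enc_expected(p.gc3s)
        dev = (exp - p.enc) / exp
        rows.append({"locus_id": p.locus_id, "genome_id": p.genome_id,
                     "gc3s": p.gc3s, "enc": p.enc, "enc_exp": exp,
                     "deviation": dev, "below": dev > margin})
    if not rows:
        raise ValueError("no genes with defined ENC and GC3s")
    table = pd.DataFrame(rows, columns=["locus_id", "genome_id", "gc3s", "enc",
                                        "enc_exp", "deviation", "below"])
    return EncPlotSummary(group_id=group_id, table=table,
                          fraction_below=float(table["below"].mean()), margin=margin)


def bias_report(profiles: list[GeneCodonProfile], group_id: str,
                margin: float = 0.05) -> pd.DataFrame:
    """One-row group summary combining the three analyses."""
    pr2 = pr2_summary(profiles, group_id)
    neut = neutrality_fit(profiles, group_id)
    encp = enc_plot(profiles, group_id, margin=margin)
    return pd.DataFrame([{
        "group_id": group_id, "n_genes": neut.n_genes,
        "pr2_mean_x": pr2.mean_point[0], "pr2_mean_y": pr2.mean_point[1],
        "pr2_q_upper_right": pr2.quadrant_counts[0],
        "pr2_q_upper_left": pr2.quadrant_counts[1],
        "pr2_q_lower_left": pr2.quadrant_counts[2],
        "pr2_q_lower_right": pr2.quadrant_counts[3],
        "neutrality_slope": neut.slope, "neutrality_intercept": neut.intercept,
        "neutrality_r2": neut.r_squared,
        "enc_fraction_below": encp.fraction_below,
    }])
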