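"""ROI aggregation, group comparison and report tables.

The statistical unit is one animal's ROI mean (per region and metric);
groups are compared with classical two-sided pooled-variance Student's
t-tests (df = n_a + n_b − 2), starred ** for p < 0.01 and *** for p < 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

FLOAT_FMT = "%.6g"


@dataclass
class RegionSummary:
    tumour_type: str
    region: str
    metric: str
    n: int
    mean: float
    sd: float


@dataclass
class TestResult:
    comparison: tuple
    t: float
    df: int
    p: float

    @property
    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        return "ns"


def roi_zspectrum(stack, mask):
    """Per-offset (mean, SD) of a Z-spectrum stack over a voxel mask."""
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vox = stack[:, mask]
    return np.nanmean(vox, axis=1), np.nanstd(vox, axis=1, ddof=0)


def ttest_unpaired(a, b, welch: bool = False) -> TestResult:
    """Two-sided Student's t-test; pooled variance unless welch=True."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        df = int(np.floor(sps.ttest_ind(a, b, equal_var=False).df))
        return TestResult(comparison=("a", "b"), t=float(t), df=df, p=float(p))
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(comparison=("a", "b"), t=float(t), df=df, p=float(p))


def tumour_volume(length_mm: float, width_mm: float) -> float:
    """Calliper volume: length × width² / 2 (mm³); requires length >= width > 0."""
    if not (length_mm >= width_mm > 0):
        raise ValueError("need length >= width > 0")
    return length_mm * width_mm**2 / 2.0


def region_summaries(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Group per-animal ROI means into (type × region × metric) summaries.

    `per_animal` columns: tumour_type, region, metric, animal, value.
    """
    rows = []
    for (ttype, region, metric), grp in per_animal.groupby(
            ["tumour_type", "region", "metric"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        rows.append(asdict(RegionSummary(ttype, region, metric,
                                         n=v.size, mean=float(v.mean()),
                                         sd=float(v.std(ddof=1))
                                         if v.size > 1 else 0.0)))
    return pd.DataFrame(rows)


def group_tests(per_animal: pd.DataFrame) -> pd.DataFrame:
    """All four comparison families of the study design, per metric.

    Within-type tumour vs necrosis (both lines) and between-type
    comparisons of each region.
    """
    comparisons = []
    for metric, grp in per_animal.groupby("metric", sort=True):
        def vals(ttype, region):
            sel = grp[(grp.tumour_type == ttype) & (grp.region == region)]
            return sel["value"].to_numpy(dtype=float)

        pairs = [
            (("22Rv1", "tumour"), ("22Rv1", "necrosis")),
            (("DU145", "tumour"), ("DU145", "necrosis")),
            (("22Rv1", "tumour"), ("DU145", "tumour")),
            (("22Rv1", "necrosis"), ("DU145", "necrosis")),
        ]
        for ga, gb in pairs:
            a, b = vals(*ga), vals(*gb)
            if a.size < 2 or b.size < 2:
                continue
            try:
                res = ttest_unpaired(a, b)
            except ValueError:
                continue
            comparisons.append({
                "metric": metric,
                "group_a": f"{ga[0]}/{ga[1]}", "group_b": f"{gb[0]}/{gb[1]}",
                "t": res.t, "df": res.df, "p": res.p, "stars": res.stars,
            })
    return pd.DataFrame(comparisons)


def build_report(per_animal: pd.DataFrame, out_dir, run_params: dict | None = None,
                 roi_spectra: pd.DataFrame | None = None) -> dict:
    """Write the report bundle: summary CSV, test CSV, optional spectra, JSON.

    Missing pieces are listed under "missing" but the report is still
    produced for whatever is available.  Output formatting is fixed so the
    bundle is byte-reproducible for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    produced, missing = [], []

    if per_animal is not None and len(per_animal):
        region_summaries(per_animal).to_csv(
            out_dir / "region_summaries.csv", index=False,
            float_format=FLOAT_FMT)
        tests = group_tests(per_animal)
        tests.to_csv(out_dir / "group_tests.csv", index=False,
                     float_format=FLOAT_FMT)
        produced += ["region_summaries.csv", "group_tests.csv"]
    else:
        missing.append("per_animal")

    if roi_spectra is not None and len(roi_spectra):
        roi_spectra.to_csv(out_dir / "roi_zspectra.csv", index=False,
                           float_format=FLOAT_FMT)
        produced.append("roi_zspectra.csv")
    else:
        missing.append("roi_spectra")

    manifest = {"produced": produced, "missing": missing,
                "run_params": run_params or {}}
    (out_dir / "report.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def simulate_comparison_power(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                              n_replicates: int = 100, seed: int = 0,
                              alpha: float = 0.001) -> float:
    """Fraction of simulated cohort pairs whose pooled t-test has p < alpha.

    Cohorts are Gaussian per-animal ROI means at the stated group
    means/SDs — the power (or, with equal parameters, the type-I error) of
    the study's comparison at its sample sizes.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a = rng.normal(mean_a, sd_a, n_a)
        b = rng.normal(mean_b, sd_b, n_b)
        if ttest_unpaired(a, b).p < alpha:
            hits += 1
    return hits / n_replicates
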