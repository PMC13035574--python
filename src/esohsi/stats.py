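"""Group comparisons of physiological parameters and report assembly.

The analysis unit is the per-patient region mean (one value per patient
per tissue class), not the pixel — pixels within a patient are strongly
correlated and would pseudo-replicate.  The default test is Welch's
unequal-variance t-test; a pooled-variance Student variant is available
by configuration.  Stars follow the strict conventions *p < 0.05,
**p < 0.01, ***p < 0.001, with no multiple-testing correction by default
(a Holm option exists).

The four standard comparison designs are:

    A  healthy stomach   vs cancer           (all patients)
    B  healthy esophagus vs cancer           (all patients)
    C  stage T1/T2 vs T3/T4 within cancer regions
    D  stage T1/T2 vs T3/T4 within healthy regions

each run for each of the four indices (StO2, NIR-PI, TWI, OHI).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .physio import INDEX_NAMES

__all__ = [
    "GroupComparison",
    "welch_t_test",
    "student_t_test",
    "significance_stars",
    "compare_groups",
    "stage_null_pvalues",
    "build_report",
]

logger = logging.getLogger(__name__)

EARLY_STAGES = ("T1", "T2")
LATE_STAGES = ("T3", "T4")


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Both groups with
    zero variance and equal means return (0, n_a + n_b - 2, 1) rather
    than NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def student_t_test(a, b) -> tuple[float, float, float]:
    """Pooled-variance Student's t-test (configuration alternative)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(a.size + b.size - 2), float(p)


def significance_stars(p: float) -> str:
    """Strict star thresholds: *** p<0.001, ** p<0.01, * p<0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    index_name: str
    design: str            # one of A, B, C, D
    label: str             # human-readable group definition
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    stars: str


_DESIGNS = {
    "A": "healthy stomach vs cancer",
    "B": "healthy esophagus vs cancer",
    "C": "T1/T2 vs T3/T4 (cancer regions)",
    "D": "T1/T2 vs T3/T4 (healthy regions)",
}


def _design_samples(frame: pd.DataFrame, design: str, index_name: str):
    if design == "A":
        a = frame[frame.tissue_class == "stomach"]
        b = frame[frame.tissue_class == "cancer"]
    elif design == "B":
        a = frame[frame.tissue_class == "esophagus"]
        b = frame[frame.tissue_class == "cancer"]
    elif design in ("C", "D"):
        sub = frame[frame.tissue_class == "cancer"] if design == "C" \
            else frame[frame.tissue_class != "cancer"]
        a = sub[sub.tumor_stage.isin(EARLY_STAGES)]
        b = sub[sub.tumor_stage.isin(LATE_STAGES)]
    else:
        raise ValueError(f"unknown design {design!r}")
    # one value per patient per role: healthy designs may contribute two
    # regions per patient; average them so each patient enters once
    a_vals = a.groupby("patient_id")[index_name].mean().to_numpy()
    b_vals = b.groupby("patient_id")[index_name].mean().to_numpy()
    return a_vals, b_vals


def compare_groups(summaries, designs: str = "ABCD",
                   index_names=INDEX_NAMES, test: str = "welch",
                   holm: bool = False) -> list:
    """Run the panel designs for each physiological index.

    ``summaries`` is a tidy DataFrame (or list of RegionSummary, converted
    automatically) with columns patient_id, tissue_class, tumor_stage and
    one column per index.  Underpowered comparisons (n < 2 in either
    group) are skipped with a warning.
    """
    from .physio import summaries_to_frame

    frame = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    test_fn = {"welch": welch_t_test, "student": student_t_test}[test]
    out: list[GroupComparison] = []
    for design in designs:
        for name in index_names:
            a, b = _design_samples(frame, design, name)
            if a.size < 2 or b.size < 2:
                logger.warning("design %s / %s skipped: group sizes %d vs %d",
                               design, name, a.size, b.size)
                continue
            t, df, p = test_fn(a, b)
            out.append(GroupComparison(name, design, _DESIGNS[design],
                                       int(a.size), int(b.size),
                                       float(a.mean()), float(b.mean()),
                                       t, df, p, significance_stars(p)))
    if holm and out:
        order = np.argsort([c.p for c in out])
        m = len(out)
        adj_prev = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, max(adj_prev, (m - rank) * out[i].p))
            out[i].p = adj
            out[i].stars = significance_stars(adj)
            adj_prev = adj
    return out


def comparisons_to_frame(comparisons: list) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


# ---------------------------------------------------------------------------
# Calibration: type-I error of the stage comparison under the null

def stage_null_pvalues(n_replicates: int = 1000, n_per_group: int = 8,
                       seed: int = 0, patient_jitter_sd: float = 0.10) -> np.ndarray:
    """Null distribution of the stage-comparison p-value (design C, TWI).

    Each replicate draws per-patient cancer physiology with a zero water
    increment (no programmed stage effect), computes each patient's TWI
    from the noise-free parameter draw, and Welch-tests early vs late
    stage groups.  Runs at the parameter level — rendering full cubes
    would not change the null distribution of per-patient region means.
    """
    from .phantom import DEFAULT_CLASS_PARAMS, draw_patient_params, default_wavelengths
    from .hsi_io import LABEL_CANCER
    from .phantom import reflectance_template
    from .physio import index_from_spectrum

    rng = np.random.default_rng(seed)
    wl = default_wavelengths()
    base = DEFAULT_CLASS_PARAMS[LABEL_CANCER]
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        twi = np.empty(2 * n_per_group)
        for i in range(2 * n_per_group):
            params = draw_patient_params(base, rng, patient_jitter_sd, water_increment=0.0)
            twi[i] = index_from_spectrum(reflectance_template(wl, params), wl, "TWI")
        _, _, pvals[r] = welch_t_test(twi[:n_per_group], twi[n_per_group:])
    return pvals


# ---------------------------------------------------------------------------
# Report bundle

def build_report(outdir, eval_report: dict | None = None,
                 comparisons: list | None = None,
                 summaries: pd.DataFrame | None = None,
                 config_snapshot: dict | None = None) -> dict:
    """Assemble the final artifact directory.

    Writes metric CSVs, the comparison table and the configuration
    snapshot; missing inputs are listed in the manifest rather than
    raising.  Regeneration from identical inputs yields byte-identical
    CSV/JSON contents.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"written": [], "missing": []}

    if eval_report is not None:
        rows: pd.DataFrame = eval_report["rows"]
        rows.to_csv(outdir / "metrics_per_patient.csv", index=False)
        summary = {"per_class": eval_report["per_class"], "macro": eval_report["macro"]}
        (outdir / "metrics_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["written"] += ["metrics_per_patient.csv", "metrics_summary.json"]
    else:
        manifest["missing"].append("evaluation report")

    if comparisons is not None:
        comparisons_to_frame(comparisons).to_csv(outdir / "group_comparisons.csv", index=False)
        manifest["written"].append("group_comparisons.csv")
    else:
        manifest["missing"].append("group comparisons")

    if summaries is not None:
        summaries.to_csv(outdir / "region_summaries.csv", index=False)
        manifest["written"].append("region_summaries.csv")
    else:
        manifest["missing"].append("region summaries")

    if config_snapshot is not None:
        (outdir / "config.json").write_text(json.dumps(config_snapshot, indent=2, sort_keys=True))
        manifest["written"].append("config.json")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
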