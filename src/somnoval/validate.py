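"""End-to-end validation pipeline and report bundle.

Orchestrates, over a collection of paired (reference, device) nights:
per-night epoch-by-epoch agreement and pooled confusion matrices;
per-night sleep parameters for both raters and their per-subject means;
5%-trimmed absolute-agreement ICC per parameter; repeated-measures
Bland–Altman over all nights; and the tabular report files (agreement
tables, confusion matrices, difference/mean point exports for
Bland–Altman plots, and a JSON summary).

The ICC is computed on per-subject means (one point per subject) while
Bland–Altman uses every night with the subject replicate structure —
two deliberate granularities.  All randomness lives in the cohort
generator; this path is deterministic given its inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import agreement, ebe, sleep_parameters as sp
from .hypnogram import PairedNight, STAGES_4

#: Parameters entering the ICC / Bland-Altman tables, in display order.
AGREEMENT_PARAMETERS = ["tst_min", "se_pct", "waso_min", "sl_min",
                        "lps_min", "reml_min", "wake_min", "n12_min",
                        "n3_min", "nrem_min", "rem_min"]


@dataclass
class ValidationReport:
    """All tables produced by one validation run."""

    icc_table: pd.DataFrame          # per group x parameter
    bland_altman_table: pd.DataFrame
    ebe_table: pd.DataFrame          # per group summary metrics
    ebe_per_night: pd.DataFrame
    confusion: dict[str, ebe.ConfusionMatrix]
    points: pd.DataFrame             # per-night (mean, difference) pairs
    metadata: dict


def _groups_of(pairs: list[PairedNight]) -> dict[str, list[PairedNight]]:
    """Group blocks: 'all', each group present, and 'pathologies' when
    more than one non-healthy group contributes nights."""
    blocks: dict[str, list[PairedNight]] = {"all": list(pairs)}
    for p in pairs:
        blocks.setdefault(p.group, []).append(p)
    patho = [p for p in pairs if p.group != "healthy"]
    if patho and len({p.group for p in patho}) > 1:
        blocks["pathologies"] = patho
    return blocks


def run_validation(pairs: Iterable[PairedNight],
                   persistent_window_min: float = 10.0,
                   trim_fraction: float = 0.05,
                   z: float = 1.96,
                   lps_single_stage: bool = False,
                   metadata: Mapping | None = None) -> ValidationReport:
    """Run the full agreement analysis over paired nights."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no paired nights supplied")
    blocks = _groups_of(pairs)

    # --- epoch-by-epoch agreement -------------------------------------
    ebe_rows, conf = [], {}
    per_night_all = None
    for gname, gpairs in blocks.items():
        table, mean, pooled = ebe.per_night_summary(gpairs)
        conf[gname] = pooled
        if gname == "all":
            per_night_all = table
        ebe_rows.append({
            "group": gname, "n_nights": len(gpairs),
            "accuracy2_pct": mean.accuracy2_pct, "kappa2": mean.kappa2,
            "kappa2_rating": ebe.landis_koch_rating(mean.kappa2),
            "sensitivity_pct": mean.sensitivity_pct,
            "specificity_pct": mean.specificity_pct,
            "accuracy4_pct": mean.accuracy4_pct, "kappa4": mean.kappa4,
            "kappa4_rating": ebe.landis_koch_rating(mean.kappa4)})
    ebe_table = pd.DataFrame(ebe_rows)

    # --- per-night sleep parameters for both raters -------------------
    rows, points_rows = [], []
    for p in pairs:
        ref_p = sp.compute_sleep_parameters(p.ref, persistent_window_min,
                                            lps_single_stage)
        dev_p = sp.compute_sleep_parameters(p.test, persistent_window_min,
                                            lps_single_stage)
        for name in AGREEMENT_PARAMETERS:
            r, d = getattr(ref_p, name), getattr(dev_p, name)
            rows.append({"subject_id": p.subject_id, "night_id": p.night_id,
                         "group": p.group, "parameter": name,
                         "reference_value": r, "device_value": d})
            if not (math.isnan(r) or math.isnan(d)):
                points_rows.append({
                    "parameter": name, "group": p.group,
                    "subject_id": p.subject_id, "night_id": p.night_id,
                    "mean": (r + d) / 2.0, "difference": r - d})
    night_values = pd.DataFrame(rows)
    points = pd.DataFrame(points_rows)

    # --- subject-level ICC and night-level Bland-Altman ---------------
    icc_rows, ba_rows = [], []
    group_of_subject = {p.subject_id: p.group for p in pairs}
    for gname, gpairs in blocks.items():
        gsubjects = {p.subject_id for p in gpairs}
        gvals = night_values[night_values["subject_id"].isin(gsubjects)]
        for name in AGREEMENT_PARAMETERS:
            pv = gvals[gvals["parameter"] == name]
            # per-subject available-case means, one point per subject
            subj = pv.groupby("subject_id")[
                ["reference_value", "device_value"]].mean().dropna()
            icc_rows.append(_icc_row(gname, name, subj, trim_fraction))
            ba_rows.append(_ba_row(gname, name, pv, z))
    icc_table = pd.DataFrame(icc_rows)
    ba_table = pd.DataFrame(ba_rows)

    meta = {"n_nights": len(pairs),
            "n_subjects": len({p.subject_id for p in pairs}),
            "groups": {g: len(ps) for g, ps in blocks.items()},
            "trim_fraction": trim_fraction, "z": z,
            "persistent_window_min": persistent_window_min}
    if metadata:
        meta.update(dict(metadata))
    return ValidationReport(icc_table=icc_table, bland_altman_table=ba_table,
                            ebe_table=ebe_table, ebe_per_night=per_night_all,
                            confusion=conf, points=points, metadata=meta)


def _icc_row(gname: str, name: str, subj: pd.DataFrame,
             trim_fraction: float) -> dict:
    ref = subj["reference_value"].to_numpy()
    dev = subj["device_value"].to_numpy()
    row = {"group": gname, "parameter": name, "n_subjects": ref.size,
           "psg_mean": float(np.mean(ref)) if ref.size else math.nan,
           "psg_sd": float(np.std(ref, ddof=1)) if ref.size > 1
           else math.nan,
           "device_mean": float(np.mean(dev)) if dev.size else math.nan,
           "device_sd": float(np.std(dev, ddof=1)) if dev.size > 1
           else math.nan}
    if ref.size >= 3:
        keep = agreement.trim_by_difference(ref, dev, trim_fraction)
        res = agreement.icc_absolute_agreement_avg(
            ref[keep], dev[keep], n_trimmed=ref.size - keep.size)
        row.update({"icc": res.estimate, "icc_lower": res.ci_lower,
                    "rating": res.rating, "n_trimmed": res.n_trimmed})
    else:
        row.update({"icc": math.nan, "icc_lower": math.nan,
                    "rating": "", "n_trimmed": 0})
    return row


def _ba_row(gname: str, name: str, pv: pd.DataFrame, z: float) -> dict:
    data: dict[str, list[tuple[float, float]]] = {}
    for _, r in pv.iterrows():
        if math.isnan(r["reference_value"]) or math.isnan(r["device_value"]):
            continue
        data.setdefault(r["subject_id"], []).append(
            (r["reference_value"], r["device_value"]))
    row = {"group": gname, "parameter": name,
           "n_subjects": len(data),
           "n_nights": sum(len(v) for v in data.values())}
    if len(data) >= 2:
        res = agreement.bland_altman_replicates(data, z=z)
        row.update({
            "bias": res.bias, "bias_ci_low": res.bias_ci[0],
            "bias_ci_high": res.bias_ci[1],
            "interpretation": agreement.sign_convention(res.bias),
            "loa_lower": res.loa_lower, "loa_upper": res.loa_upper,
            "loa_lower_ci_low": res.loa_lower_ci[0],
            "loa_lower_ci_high": res.loa_lower_ci[1],
            "loa_upper_ci_low": res.loa_upper_ci[0],
            "loa_upper_ci_high": res.loa_upper_ci[1],
            "s_between": res.s_between, "s_within": res.s_within,
            "m_harmonic": res.m_harmonic, "sd_total": res.sd_total})
    else:
        row.update({k: math.nan for k in
                    ("bias", "bias_ci_low", "bias_ci_high", "loa_lower",
                     "loa_upper", "loa_lower_ci_low", "loa_lower_ci_high",
                     "loa_upper_ci_low", "loa_upper_ci_high", "s_between",
                     "s_within", "m_harmonic", "sd_total")})
        row["interpretation"] = ""
    return row


def export_bland_altman_points(report: ValidationReport, parameter: str,
                               group: str = "all",
                               path: str | Path | None = None
                               ) -> pd.DataFrame:
    """Per-night (mean, difference) pairs for one parameter and group.

    Differences are reference minus device (positive = device
    underestimates).  When ``path`` is given, writes a CSV whose header
    comment echoes the bias and limits of agreement for that block.
    """
    if parameter not in AGREEMENT_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    pts = report.points[report.points["parameter"] == parameter]
    if group != "all":
        pts = pts[pts["group"] == group]
    pts = pts[["mean", "difference", "subject_id", "night_id", "group"]]
    if path is not None:
        ba = report.bland_altman_table
        row = ba[(ba["parameter"] == parameter) & (ba["group"] == group)]
        with open(path, "w", encoding="utf-8") as fh:
            if len(row):
                r = row.iloc[0]
                fh.write(f"# parameter={parameter} group={group} "
                         f"bias={r['bias']:.9g} "
                         f"loa_lower={r['loa_lower']:.9g} "
                         f"loa_upper={r['loa_upper']:.9g}\n")
            pts.to_csv(fh, index=False, lineterminator="\n")
    return pts.reset_index(drop=True)


def _fmt_confusion(m: ebe.ConfusionMatrix) -> pd.DataFrame:
    """Row-normalized percentages (1 decimal) with prevalence and
    one-vs-rest accuracy columns, reference stages in rows."""
    rn = m.row_normalized * 100.0
    df = pd.DataFrame(np.round(rn, 1), index=STAGES_4,
                      columns=[f"device_{s}" for s in STAGES_4])
    df.insert(0, "prevalence_pct", np.round(m.prevalence * 100.0, 1))
    df["accuracy_pct"] = [round(ebe.stage_accuracy_one_vs_rest(m, s), 1)
                          for s in STAGES_4]
    df.index.name = "psg_stage"
    return df


def write_report(report: ValidationReport, out_dir: str | Path) -> None:
    """Write the report bundle: TSV tables, confusion matrices, point
    CSVs for the six conventionally plotted parameters, and a JSON
    summary.  Percentages carry 1 decimal, kappa/ICC 2 decimals, minutes
    1 decimal in the formatted tables; full-precision tables are written
    alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.icc_table.to_csv(out / "icc_table.tsv", sep="\t", index=False,
                            float_format="%.6g", lineterminator="\n")
    report.bland_altman_table.to_csv(out / "bland_altman_table.tsv",
                                     sep="\t", index=False,
                                     float_format="%.6g",
                                     lineterminator="\n")
    report.ebe_table.to_csv(out / "ebe_table.tsv", sep="\t", index=False,
                            float_format="%.6g", lineterminator="\n")
    report.ebe_per_night.to_csv(out / "ebe_per_night.tsv", sep="\t",
                                index=False, float_format="%.6g",
                                lineterminator="\n")
    for gname, m in report.confusion.items():
        _fmt_confusion(m).to_csv(out / f"confusion_{gname}.tsv", sep="\t",
                                 lineterminator="\n")
        pd.DataFrame(m.counts, index=STAGES_4, columns=STAGES_4).to_csv(
            out / f"confusion_counts_{gname}.tsv", sep="\t",
            lineterminator="\n")
    for param in ("se_pct", "sl_min", "waso_min", "n12_min", "n3_min",
                  "rem_min"):
        export_bland_altman_points(report, param, "all",
                                   out / f"points_{param}.csv")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
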