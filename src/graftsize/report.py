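"""Study report: the full analysis pipeline on one cohort.

``build_report`` runs prediction → agreement → reproducibility →
descriptive comparison on a cohort and returns a JSON-serialisable dict:
cohort summary, predicted/actual graft summaries with per-size frequency
tables, the agreement block (concordance with exact CIs and weighted
kappa), four Bland–Altman blocks, and the Wilcoxon comparison of rounded
predicted vs actual sizes.  Numbers carry full precision; display rounding
(integer percents, two-decimal mm and kappa) happens only in
``render_markdown``.

The report is a pure function of the cohort and options, so identical
inputs give byte-identical JSON; callers wanting a timestamp add it
themselves (the CLI does, outside the reproducible payload).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from typing import Mapping

from . import __version__
from .agreement import AgreementResult, agreement_summary, round_percent
from .cohort import Cohort, Session, Sex, Side, validate_cohort
from .descriptive import median_iqr, wilcoxon_signed_rank
from .prediction import PredictionSet, predict_cohort, predict_cohort_consensus
from .reproducibility import reproducibility_report

logger = logging.getLogger("graftsize")


def _frequency_table(values) -> dict[str, int]:
    return {str(k): v for k, v in sorted(Counter(values).items())}


def build_report(
    cohort: Cohort,
    reader: str | None = None,
    session: Session | str = Session.T0,
    consensus: bool = False,
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> dict:
    """Run the full analysis pipeline and assemble the report dict."""
    session = Session(session)
    n = len(cohort)

    ages = [r.age_years for r in cohort.records]
    cohort_block = {
        "n": n,
        "sex_counts": {
            "M": sum(r.sex is Sex.M for r in cohort.records),
            "F": sum(r.sex is Sex.F for r in cohort.records),
        },
        "side_counts": {
            "left": sum(r.side is Side.LEFT for r in cohort.records),
            "right": sum(r.side is Side.RIGHT for r in cohort.records),
        },
        "age_years": median_iqr(ages).as_dict() if ages else None,
        "validation_violations": validate_cohort(cohort),
    }

    if consensus:
        pset: PredictionSet = predict_cohort_consensus(cohort, session=session)
        mode = "consensus"
    else:
        pset = predict_cohort(cohort, reader=reader, session=session)
        mode = f"reader={reader or cohort.readers[0]!s}, session={session.value}"

    raw = [p.pgd_raw_mm for p in pset.predictions.values()]
    rounded = [p.pgd_rounded_mm for p in pset.predictions.values()]
    predicted_block = {
        "mode": mode,
        "n": len(pset.predictions),
        "excluded": dict(pset.excluded),
        "raw_mm": median_iqr(raw).as_dict() if raw else None,
        "rounded_mm": median_iqr([float(v) for v in rounded]).as_dict() if rounded else None,
        "rounded_frequency": _frequency_table(rounded),
    }

    # (predicted, actual) pairs restricted to patients with a known actual size
    pairs = []
    skipped_no_actual = []
    for pid, pred in pset.predictions.items():
        actual = cohort.record(pid).actual_graft_mm
        if actual is None:
            skipped_no_actual.append(pid)
        else:
            pairs.append((pred.pgd_rounded_mm, actual))
    if skipped_no_actual:
        logger.info(
            "agreement: skipped %d records without actual graft size",
            len(skipped_no_actual),
        )

    actuals = [a for _, a in pairs]
    actual_block = {
        "n": len(actuals),
        "skipped_no_actual": skipped_no_actual,
        "mm": median_iqr([float(a) for a in actuals]).as_dict() if actuals else None,
        "frequency": _frequency_table(actuals),
    }

    agreement_block = None
    wilcoxon_block = None
    if pairs:
        agreement_block = agreement_summary(
            pairs, level=level, ci_method=ci_method
        ).as_dict()
        wilcoxon_block = wilcoxon_signed_rank(
            [float(p) for p, _ in pairs], [float(a) for _, a in pairs]
        ).as_dict()
        wilcoxon_block["comparison"] = "rounded predicted vs actual graft diameter"

    repro = None
    try:
        repro_results = reproducibility_report(cohort, inter_session=session)
        repro = {
            f"{tendon}_{kind}": res.as_dict()
            for (tendon, kind), res in repro_results.items()
        }
        repro["excluded_n"] = repro_results.excluded_n
    except ValueError as exc:
        logger.info("reproducibility skipped: %s", exc)

    return {
        "schema_version": 1,
        "software": {"name": "graftsize", "version": __version__},
        "provenance": dict(cohort.metadata),
        "cohort": cohort_block,
        "predicted": predicted_block,
        "actual": actual_block,
        "agreement": agreement_block,
        "wilcoxon": wilcoxon_block,
        "reproducibility": repro,
    }


def report_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def _fmt_pct_ci(pct: float, ci) -> str:
    return f"{round_percent(pct)}% (95% CI {round_percent(ci[0])}–{round_percent(ci[1])}%)"


def render_markdown(report: Mapping) -> str:
    """Human-readable summary with display rounding applied."""
    lines = ["# Graft size prediction report", ""]
    c = report["cohort"]
    lines.append(f"Patients: {c['n']} "
                 f"(M {c['sex_counts']['M']} / F {c['sex_counts']['F']}; "
                 f"left {c['side_counts']['left']} / right {c['side_counts']['right']})")
    if c["age_years"]:
        a = c["age_years"]
        lines.append(
            f"Median age {a['median']:.0f} years (IQR {a['q1']:.0f}–{a['q3']:.0f})"
        )
    p = report["predicted"]
    if p["raw_mm"]:
        r = p["raw_mm"]
        lines += [
            "",
            "## Predicted vs actual graft diameter",
            "",
            f"Prediction mode: {p['mode']} (n = {p['n']}, excluded {len(p['excluded'])})",
            f"Median predicted (raw) {r['median']:.2f} mm "
            f"(IQR {r['q1']:.2f}–{r['q3']:.2f} mm)",
        ]
    act = report["actual"]
    if act["mm"]:
        m = act["mm"]
        lines.append(
            f"Median actual {m['median']:.2f} mm (IQR {m['q1']:.2f}–{m['q3']:.2f} mm)"
        )
    ag = report["agreement"]
    if ag:
        lines += [
            "",
            f"Concordance: {ag['n_concordant']}/{ag['n']} "
            + _fmt_pct_ci(ag["concordance_pct"], ag["concordance_ci_pct"]),
            f"Under-prediction: {ag['n_under']}/{ag['n']} "
            + _fmt_pct_ci(ag["under_pct"], ag["under_ci_pct"]),
            f"Over-prediction: {ag['n_over']}/{ag['n']} "
            + _fmt_pct_ci(ag["over_pct"], ag["over_ci_pct"]),
        ]
        if ag["kappa"] is not None:
            lines.append(
                f"Linearly weighted κ = {ag['kappa']:.2f} ({ag['kappa_band']})"
            )
        else:
            lines.append(f"Linearly weighted κ: {ag['kappa_band']}")
    w = report["wilcoxon"]
    if w:
        p_txt = "n.s." if w["degenerate"] or w["p_value"] >= 0.05 else f"p = {w['p_value']:.3f}"
        lines.append(f"Wilcoxon signed-rank ({w['comparison']}): {p_txt}")
    repro = report["reproducibility"]
    if repro:
        lines += ["", "## Reproducibility (Bland–Altman)", ""]
        for key in ("ST_intra", "GT_intra", "ST_inter", "GT_inter"):
            if key in repro:
                b = repro[key]
                tendon, kind = key.split("_")
                lines.append(
                    f"{tendon} {kind}-reader: bias {b['bias_mm']:.2f} mm, "
                    f"CoR {b['cor_mm']:.2f} mm"
                )
    lines.append("")
    return "\n".join(lines)
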