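"""End-to-end linking pipeline: wide CSV in, agreement report + plots out.

Input is a wide table with columns ``item1..item4`` and, for validation
runs (which need the directly derived score), ``item5``; one respondent per
row, responses coded 1-7.  An optional grouping column (e.g. injury type)
yields one report row per group in addition to the overall row.  Rows that
fail validation are collected with their reason; by default the run refuses
to proceed if any row is malformed, since silently dropping cases would
bias the agreement statistics — pass ``skip_invalid`` to drop them loudly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementReport, PairedScores, agreement_report, limits_of_agreement, difference_stats
from .scoring import classify, prorated_score, score_pair, validate_responses

logger = logging.getLogger("swlslink")

__all__ = [
    "ITEM_COLUMNS",
    "RunConfig",
    "InvalidRowsError",
    "read_responses_csv",
    "score_frame",
    "build_reports",
    "run_linking_report",
    "write_report_json",
    "write_report_csv",
    "worked_example_fixtures",
]

ITEM_COLUMNS = ("item1", "item2", "item3", "item4", "item5")


class InvalidRowsError(ValueError):
    """Raised when the input contains malformed rows and skipping is off."""

    def __init__(self, bad_rows: list[tuple[int, str]]):
        self.bad_rows = bad_rows
        preview = "; ".join(f"row {i}: {r}" for i, r in bad_rows[:5])
        more = "" if len(bad_rows) <= 5 else f" (+{len(bad_rows) - 5} more)"
        super().__init__(f"{len(bad_rows)} malformed row(s): {preview}{more}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one report run.

    Display rounding (``score_decimals`` for score columns,
    ``corr_decimals`` for correlations/ICCs) applies to formatted output
    only and never feeds back into computation.
    """

    input_path: str
    group: str | None = None
    out_json: str | None = None
    out_csv: str | None = None
    plot: str | None = None
    score_decimals: int = 1
    corr_decimals: int = 2
    alpha: float = 0.05
    skip_invalid: bool = False
    jitter: float = 0.0
    seed: int = 0


def read_responses_csv(
    path: str | Path,
    require_item5: bool = False,
    group: str | None = None,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Read and validate a wide SWLS response CSV.

    Returns the validated rows (integer item columns, plus the group column
    if requested).  Every rejected row is logged with its reason; with
    ``skip_invalid=False`` any rejection aborts the run.
    """
    df = pd.read_csv(path)
    has5 = "item5" in df.columns
    cols = list(ITEM_COLUMNS if has5 else ITEM_COLUMNS[:4])
    missing = [c for c in ITEM_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    if require_item5 and not has5:
        raise ValueError("this run needs item5 (directly derived scores); column absent")
    if group is not None and group not in df.columns:
        raise ValueError(f"grouping column {group!r} not found in input")

    bad: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df[cols].itertuples(index=False, name=None)):
        try:
            vals = [None if pd.isna(v) else (int(v) if float(v).is_integer() else v)
                    for v in row]
            validate_responses(vals)
        except (ValueError, TypeError) as err:
            bad.append((i, str(err)))
            keep[i] = False
    for i, reason in bad:
        logger.warning("rejected row %d: %s", i, reason)
    if bad and not skip_invalid:
        raise InvalidRowsError(bad)

    out = df.loc[keep, cols].astype(int).reset_index(drop=True)
    if group is not None:
        out[group] = df.loc[keep, group].astype(str).values
    return out


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived score columns to a validated response table.

    Adds ``sum4``, ``direct`` (when item5 present), ``prorated``,
    ``category_direct`` and ``category_prorated``.
    """
    out = df.copy()
    has5 = "item5" in out.columns
    items = out[list(ITEM_COLUMNS[: 5 if has5 else 4])].to_numpy()
    s4 = items[:, :4].sum(axis=1)
    out["sum4"] = s4
    if has5:
        out["direct"] = items.sum(axis=1)
    out["prorated"] = 1.25 * s4
    if has5:
        out["category_direct"] = [classify(s).label for s in out["direct"]]
    out["category_prorated"] = [classify(s).label for s in out["prorated"]]
    return out


def build_reports(
    scored: pd.DataFrame, group: str | None = None, alpha: float = 0.05
) -> list[AgreementReport]:
    """Overall report plus one per group value (every value kept, none dropped)."""
    if "direct" not in scored.columns:
        raise ValueError("agreement reports need 5-item rows (direct scores)")
    reports = [agreement_report(scored["direct"], scored["prorated"],
                                label="overall", alpha=alpha)]
    if group is not None:
        for value in sorted(scored[group].unique()):
            sub = scored[scored[group] == value]
            reports.append(
                agreement_report(sub["direct"], sub["prorated"],
                                 label=str(value), alpha=alpha)
            )
    return reports


def write_report_json(reports: Sequence[AgreementReport], path: str | Path) -> None:
    payload = {"reports": [r.to_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_report_csv(reports: Sequence[AgreementReport], path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)


def _plot_path(template: str, label: str) -> str:
    p = Path(template)
    return str(p.with_name(f"{p.stem}_{label.replace(' ', '-')}{p.suffix}"))


def run_linking_report(cfg: RunConfig) -> list[AgreementReport]:
    """Full pipeline: read, validate, score, report per group, write outputs."""
    df = read_responses_csv(cfg.input_path, require_item5=True,
                            group=cfg.group, skip_invalid=cfg.skip_invalid)
    scored = score_frame(df)
    reports = build_reports(scored, group=cfg.group, alpha=cfg.alpha)
    if cfg.out_json:
        write_report_json(reports, cfg.out_json)
    if cfg.out_csv:
        write_report_csv(reports, cfg.out_csv)
    if cfg.plot:
        from .plots import bland_altman_plot  # deferred: matplotlib import cost

        for rep in reports:
            mask = (scored[cfg.group] == rep.label) if (cfg.group and rep.label != "overall") \
                else np.ones(len(scored), dtype=bool)
            p = PairedScores(scored.loc[mask, "direct"].to_numpy(float),
                             scored.loc[mask, "prorated"].to_numpy(float))
            bland_altman_plot(p, limits_of_agreement(difference_stats(p)),
                              title=f"Bland-Altman: {rep.label}",
                              out_path=_plot_path(cfg.plot, rep.label),
                              jitter=cfg.jitter, seed=cfg.seed)
    return reports


def worked_example_fixtures() -> dict:
    """Packaged worked examples of the proration rule.

    ``group``: the published overall item means for items 1-4; their sum
    (the group-level 4-item mean) prorates to 20.5125, displayed as 20.5 —
    the published overall prorated group mean.  ``individual_max`` /
    ``individual_min``: all-7 and all-1 response patterns mapping to the
    scale endpoints 35 and 5.
    """
    group_item_means = (3.76, 3.80, 4.32, 4.53)
    group_sum4_mean = float(np.sum(group_item_means))
    return {
        "group": {
            "item_means": group_item_means,
            "sum4_mean": group_sum4_mean,
            "prorated_exact": 1.25 * group_sum4_mean,
            "prorated_1dp": round(1.25 * group_sum4_mean, 1),
        },
        "individual_max": {
            "responses": (7, 7, 7, 7),
            "prorated": prorated_score([7, 7, 7, 7]),
        },
        "individual_min": {
            "responses": (1, 1, 1, 1),
            "prorated": prorated_score([1, 1, 1, 1]),
        },
        "identity_example": {
            "responses": (3, 4, 5, 4, 4),  # item5 equals the mean of items 1-4
            "pair": score_pair([3, 4, 5, 4, 4]),
        },
    }
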