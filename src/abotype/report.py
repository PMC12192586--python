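"""Per-sample and per-run result files, and concordance metrics.

Mirrors the output conventions of clinical amplicon-typing runs: every
sample gets a polymorphism summary (the five diagnostic positions with their
observed symbol fractions and depth) and a phenotype summary; the run gets a
full results table including flagged samples, an export table restricted to
successfully typed samples, a run log and a dependency-versions file.

Concordance against a truth table (e.g. serology or an independent
laboratory) is summarised as a confusion matrix over {A, B, AB, O} with
overall accuracy and one-vs-rest sensitivity, specificity and precision per
phenotype; samples without an ok call are excluded and counted.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import VariantProfile
from .classify import AboCall, STATUS_OK

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("A", "B", "AB", "O")

EXPORT_COLUMNS = (
    "sample_id",
    "phenotype",
    "genotype",
    "extended_genotype",
    "reads",
    "reliability",
)


@dataclass
class RunReport:
    """Aggregated results of one pipeline run."""

    run_id: str
    version: str
    config: dict
    calls: list[AboCall]
    n_ok: int
    n_low_coverage: int
    n_unknown: int


@dataclass
class ConcordanceSummary:
    """Agreement between pipeline calls and a phenotype truth table."""

    accuracy: float
    confusion: pd.DataFrame  # rows: truth, columns: called
    per_phenotype: pd.DataFrame  # sensitivity/specificity/precision per label
    n_evaluated: int
    n_excluded: int


# ---------------------------------------------------------------------------
# Per-sample summaries
# ---------------------------------------------------------------------------

def summarize_sample(call: AboCall, profile: VariantProfile) -> tuple[str, str]:
    """Text blocks for one sample: (polymorphisms, phenotype).

    The polymorphism block lists the five diagnostic positions with their
    symbol fractions and depth; the phenotype block the typing outcome.
    Field order is stable so outputs diff cleanly between runs.
    """
    poly_lines = [f"sample_id\t{call.sample_id}"]
    for pos in sorted(profile.fractions, key=lambda p: (p.exon, p.exon_offset)):
        fracs = profile.fractions[pos]
        shown = (
            "/".join(
                f"{s}:{fracs[s]:.3f}"
                for s in sorted(fracs, key=lambda s: (-fracs[s], s))
            )
            or "-"
        )
        poly_lines.append(
            f"{pos.label()}\tdepth={profile.depths.get(pos, 0)}\t{shown}"
        )
    poly = "\n".join(poly_lines) + "\n"

    pheno_lines = [
        f"sample_id\t{call.sample_id}",
        f"status\t{call.status}",
        f"mode\t{call.mode}",
        f"reads\t{call.reads}",
        f"reliability\t{call.reliability}",
    ]
    if call.is_ok:
        pheno_lines += [
            f"phenotype\t{call.phenotype}",
            f"genotype\t{call.genotype}",
            f"extended_genotype\t{call.extended_genotype}",
        ]
    pheno = "\n".join(pheno_lines) + "\n"
    return poly, pheno


def write_sample_reports(
    call: AboCall, profile: VariantProfile, out_dir: str | Path
) -> None:
    """Write ABOReadPolymorphisms.txt / ABOPhenotype.txt for one sample."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    poly, pheno = summarize_sample(call, profile)
    (out_dir / "ABOReadPolymorphisms.txt").write_text(poly)
    (out_dir / "ABOPhenotype.txt").write_text(pheno)


# ---------------------------------------------------------------------------
# Run-level aggregation
# ---------------------------------------------------------------------------

def calls_to_dataframe(calls: Sequence[AboCall]) -> pd.DataFrame:
    """One row per sample, ordered by sample id."""
    rows = []
    for call in sorted(calls, key=lambda c: c.sample_id):
        rows.append(
            {
                "sample_id": call.sample_id,
                "status": call.status,
                "phenotype": call.phenotype or "",
                "genotype": call.genotype or "",
                "extended_genotype": call.extended_genotype or "",
                "reads": call.reads,
                "reliability": call.reliability,
                "mode": call.mode,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "status", "phenotype", "genotype",
            "extended_genotype", "reads", "reliability", "mode",
        ],
    )


def _package_versions() -> dict[str, str]:
    versions = {}
    for pkg in ("abotype", "biopython", "numpy", "pandas", "click"):
        try:
            versions[pkg] = metadata.version(pkg)
        except metadata.PackageNotFoundError:  # pragma: no cover
            versions[pkg] = "unknown"
    return versions


def aggregate_run(
    calls: Sequence[AboCall],
    out_dir: str | Path,
    config: Mapping | None = None,
    run_id: str = "run",
    timestamps: bool = True,
    excel: bool = False,
) -> RunReport:
    """Write run-level result files and return the aggregated report.

    ``ABO_result.csv`` contains every sample with its status;
    ``final_export.csv`` only successfully typed samples (flagged samples
    are routed to repeat testing instead).  Pass ``timestamps=False`` for
    byte-reproducible logs.
    """
    if not calls:
        raise ValueError("aggregate_run requires at least one call")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})

    table = calls_to_dataframe(calls)
    table.to_csv(out_dir / "ABO_result.csv", index=False)
    if excel:
        table.to_excel(out_dir / "ABO_result.xlsx", index=False)

    export = table[table["status"] == STATUS_OK].loc[:, list(EXPORT_COLUMNS)]
    export.to_csv(out_dir / "final_export.csv", index=False)

    versions = _package_versions()
    with open(out_dir / "versions.yml", "w") as fh:
        for pkg, ver in versions.items():
            fh.write(f"{pkg}: {ver}\n")

    n_ok = int((table["status"] == STATUS_OK).sum())
    n_low = int((table["status"] == "low_coverage").sum())
    n_unknown = int((table["status"] == "unknown").sum())

    log_lines = [f"run_id: {run_id}", f"abotype version: {versions['abotype']}"]
    if timestamps:
        log_lines.append(f"completed: {_dt.datetime.now().isoformat()}")
    log_lines += [f"config.{k}: {v}" for k, v in sorted(config.items())]
    log_lines += [
        f"samples: {len(calls)}",
        f"ok: {n_ok}",
        f"low_coverage: {n_low}",
        f"unknown: {n_unknown}",
    ]
    (out_dir / "ABO_result.log").write_text("\n".join(log_lines) + "\n")

    return RunReport(
        run_id=run_id,
        version=versions["abotype"],
        config=config,
        calls=list(calls),
        n_ok=n_ok,
        n_low_coverage=n_low,
        n_unknown=n_unknown,
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance_report(
    calls: Sequence[AboCall], truth: Mapping[str, str]
) -> ConcordanceSummary:
    """Compare ok calls against a sample_id → phenotype truth table.

    Non-ok calls and samples missing from the truth table are excluded from
    the metrics and counted in ``n_excluded``.  Per-phenotype metrics are
    one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
    TP/(TP+FP); undefined ratios are NaN.
    """
    pairs = []
    excluded = 0
    for call in calls:
        if not call.is_ok:
            excluded += 1
            continue
        expected = truth.get(call.sample_id)
        if expected is None:
            logger.warning("truth table lacks sample %s; excluded", call.sample_id)
            excluded += 1
            continue
        pairs.append((expected, call.phenotype))

    labels = list(PHENOTYPE_LABELS)
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for expected, called in pairs:
        confusion.loc[expected, called] += 1

    total = len(pairs)
    accuracy = float(np.trace(confusion.to_numpy()) / total) if total else float("nan")

    metrics = {}
    mat = confusion.to_numpy()
    for i, label in enumerate(labels):
        tp = mat[i, i]
        fn = mat[i, :].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = mat.sum() - tp - fn - fp
        metrics[label] = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    per_phenotype = pd.DataFrame(metrics).T

    return ConcordanceSummary(
        accuracy=accuracy,
        confusion=confusion,
        per_phenotype=per_phenotype,
        n_evaluated=total,
        n_excluded=excluded,
    )


def read_truth_table(path: str | Path) -> dict[str, str]:
    """Read a truth CSV with columns sample_id (or sample) and phenotype."""
    df = pd.read_csv(path)
    key = "sample_id" if "sample_id" in df.columns else "sample"
    return dict(zip(df[key].astype(str), df["phenotype"].astype(str)))
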