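"""Published study inputs and the round-trip reproduction of its PAR table.

The source study reports, for the Indonesian adult population, PAR
percentages (with 95% CIs) of CHD and stroke attributable to five
modifiable risk factors, by sex and by age group.  Its inputs were
(a) national risk-factor prevalences from the Riskesdas 2013 survey and
(b) Asia-Pacific cohort relative risks — but only a handful of
prevalences are printed as numbers in the text, and the relative risks
are not printed at all.

This module therefore packages:

* the five prevalences printed in the text (smoking in men 64.9% and
  women 2.1%, elevated total cholesterol in women 39.6%, diabetes in
  men 5.6% and women 7.7%);
* the full published PAR table (point estimates and CI bounds, percent
  scale);
* relative-risk fixtures *back-derived* from the published PARs via the
  inverse of Levin's formula, tagged ``derived`` — these stand in for
  the unpublished cohort estimates and are synthetic by construction;
* an end-to-end reproduction that recomputes every reportable cell from
  prevalence + derived RR and diffs against the printed value.

Prevalences shown only in the study's bar charts (hypertension and
excess body weight, and all age-group prevalences) are deliberately
*not* digitised; those rows are marked unavailable and excluded from
reproduction runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .levin import (
    ExposurePrevalence,
    RelativeRiskEstimate,
    format_percent,
    invert_rr,
    levin_par,
)

__all__ = [
    "FACTORS",
    "OUTCOMES",
    "STRATA",
    "load_prevalence_fixture",
    "lookup_prevalence",
    "load_study_table",
    "derive_implied_rr_table",
    "reproduce_reportable_cells",
    "write_fixture_files",
    "read_fixture_file",
]

FACTORS = (
    "smoking",
    "hypertension",
    "elevated total cholesterol",
    "excess body weight",
    "diabetes",
)
OUTCOMES = ("CHD", "all stroke", "ischaemic stroke", "haemorrhagic stroke")
STRATA = ("men", "women", "<55 years", ">=55 years")

# Prevalences printed as numbers in the study text (proportion scale).
_PRINTED_PREVALENCES = {
    ("smoking", "men"): 0.649,
    ("smoking", "women"): 0.021,
    ("elevated total cholesterol", "women"): 0.396,
    ("diabetes", "men"): 0.056,
    ("diabetes", "women"): 0.077,
}

# Published PAR table: {outcome: {factor: {stratum: (point, lo, hi)}}},
# percent scale exactly as printed (negatives retained).
_PAR_TABLE = {
    "CHD": {
        "smoking": {
            "men": (25.1, 16.3, 32.8),
            "women": (1.4, 0.7, 2.3),
            "<55 years": (20.3, 13.2, 27.9),
            ">=55 years": (10.6, 5.0, 15.7),
        },
        "hypertension": {
            "men": (19.7, 16.3, 23.6),
            "women": (25.3, 18.1, 32.6),
            "<55 years": (32.9, 28.7, 37.5),
            ">=55 years": (33.1, 26.6, 39.0),
        },
        "elevated total cholesterol": {
            "men": (19.0, 14.2, 23.9),
            "women": (17.8, 7.2, 27.3),
            "<55 years": (25.3, 20.0, 31.6),
            ">=55 years": (17.7, 8.5, 25.7),
        },
        "excess body weight": {
            "men": (9.4, 6.0, 12.7),
            "women": (10.4, 2.2, 19.2),
            "<55 years": (19.6, 14.1, 25.1),
            ">=55 years": (3.3, -0.3, 7.9),
        },
        "diabetes": {
            "men": (4.2, 2.3, 6.3),
            "women": (10.7, 5.1, 17.6),
            "<55 years": (7.9, 5.3, 11.0),
            ">=55 years": (8.4, 3.9, 13.8),
        },
    },
    "all stroke": {
        "smoking": {
            "men": (16.7, 11.7, 21.8),
            "women": (0.6, 0.2, 1.0),
            "<55 years": (11.1, 6.2, 15.4),
            ">=55 years": (3.7, 0.5, 6.7),
        },
        "hypertension": {
            "men": (37.2, 34.8, 39.6),
            "women": (38.9, 34.7, 42.9),
            "<55 years": (49.0, 46.5, 51.6),
            ">=55 years": (52.9, 49.6, 56.3),
        },
        "elevated total cholesterol": {
            "men": (3.9, 1.1, 7.0),
            "women": (6.9, 1.3, 12.5),
            "<55 years": (10.3, 7.0, 13.7),
            ">=55 years": (2.2, -3.7, 7.5),
        },
        "excess body weight": {
            "men": (5.4, 3.2, 7.4),
            "women": (8.2, 3.4, 12.5),
            "<55 years": (14.6, 11.1, 17.9),
            ">=55 years": (0.4, -1.8, 2.8),
        },
        "diabetes": {
            "men": (3.8, 2.6, 5.0),
            "women": (7.1, 3.9, 10.5),
            "<55 years": (6.3, 4.8, 7.9),
            ">=55 years": (5.8, 2.8, 8.8),
        },
    },
    "ischaemic stroke": {
        "smoking": {
            "men": (25.1, 16.6, 33.3),
            "women": (0.6, 0.1, 1.3),
            "<55 years": (14.4, 6.8, 23.1),
            ">=55 years": (7.1, 2.1, 12.6),
        },
        "hypertension": {
            "men": (29.3, 25.1, 33.0),
            "women": (37.3, 30.8, 43.9),
            "<55 years": (38.2, 33.5, 43.4),
            ">=55 years": (53.2, 47.6, 58.3),
        },
        "elevated total cholesterol": {
            "men": (10.1, 5.6, 15.0),
            "women": (10.1, 0.4, 19.9),
            "<55 years": (19.3, 13.6, 24.9),
            ">=55 years": (2.6, -5.4, 11.6),
        },
        "excess body weight": {
            "men": (10.6, 7.2, 14.2),
            "women": (15.1, 7.7, 22.2),
            "<55 years": (22.7, 17.4, 28.6),
            ">=55 years": (4.4, 0.9, 8.1),
        },
        "diabetes": {
            "men": (5.3, 3.6, 7.6),
            "women": (6.0, 1.2, 12.7),
            "<55 years": (8.3, 5.7, 11.3),
            ">=55 years": (7.3, 2.6, 12.7),
        },
    },
    "haemorrhagic stroke": {
        "smoking": {
            "men": (10.6, 1.2, 19.6),
            "women": (0.6, 0.1, 1.4),
            "<55 years": (4.4, -2.9, 10.9),
            ">=55 years": (3.3, -1.7, 8.8),
        },
        "hypertension": {
            "men": (47.3, 43.1, 51.3),
            "women": (46.6, 39.7, 53.2),
            "<55 years": (61.3, 57.1, 65.2),
            ">=55 years": (56.2, 50.8, 61.6),
        },
        "elevated total cholesterol": {
            "men": (-2.6, -7.5, 2.3),
            "women": (5.7, -5.0, 16.2),
            "<55 years": (1.1, -4.2, 6.6),
            ">=55 years": (2.8, -7.5, 12.9),
        },
        "excess body weight": {
            "men": (3.8, 0.7, 7.6),
            "women": (1.9, -5.4, 9.6),
            "<55 years": (10.9, 5.1, 16.8),
            ">=55 years": (-1.2, -5.0, 3.1),
        },
        "diabetes": {
            "men": (2.3, 0.5, 4.3),
            "women": (8.4, 2.0, 17.1),
            "<55 years": (4.9, 2.5, 7.8),
            ">=55 years": (2.7, -2.6, 9.7),
        },
    },
}

#: Decimal places kept on back-derived RR fixtures.
RR_FIXTURE_DECIMALS = 4


def load_prevalence_fixture() -> list[ExposurePrevalence]:
    """Every text-printed prevalence as an :class:`ExposurePrevalence`."""
    return [
        ExposurePrevalence(factor=f, stratum=s, value=v)
        for (f, s), v in sorted(_PRINTED_PREVALENCES.items())
    ]


def lookup_prevalence(factor: str, stratum: str) -> float | None:
    """Printed prevalence for a factor/stratum, or ``None`` if the study
    shows it only graphically (never digitised here)."""
    return _PRINTED_PREVALENCES.get((factor, stratum))


def load_study_table() -> pd.DataFrame:
    """The published PAR table as a tidy DataFrame.

    Columns: factor, outcome, stratum, par_point / par_ci_lower /
    par_ci_upper (percent scale as printed), pe (proportion, NaN when
    only shown graphically), pe_available.
    """
    rows = []
    for outcome, by_factor in _PAR_TABLE.items():
        for factor, by_stratum in by_factor.items():
            for stratum, (point, lo, hi) in by_stratum.items():
                pe = lookup_prevalence(factor, stratum)
                rows.append(
                    {
                        "factor": factor,
                        "outcome": outcome,
                        "stratum": stratum,
                        "par_point": point,
                        "par_ci_lower": lo,
                        "par_ci_upper": hi,
                        "pe": pe,
                        "pe_available": pe is not None,
                    }
                )
    return pd.DataFrame(rows)


def derive_implied_rr_table(
    table: pd.DataFrame | None = None,
    prevalences: dict[tuple[str, str], float] | None = None,
) -> list[RelativeRiskEstimate]:
    """Back-derive RR fixtures from published PARs via inverse Levin.

    For every table row whose prevalence is printed, the RR point and
    CI bounds are ``invert_rr`` of the printed PAR point and bounds at
    the printed prevalence, rounded to 4 decimals.  These are synthetic
    stand-ins for the unpublished cohort relative risks and are tagged
    as derived wherever they are persisted.
    """
    if table is None:
        table = load_study_table()
    if prevalences is None:
        prevalences = dict(_PRINTED_PREVALENCES)
    estimates = []
    for row in table.itertuples(index=False):
        pe = prevalences.get((row.factor, row.stratum))
        if pe is None:
            continue
        rr = round(invert_rr(row.par_point / 100.0, pe), RR_FIXTURE_DECIMALS)
        lo = round(invert_rr(row.par_ci_lower / 100.0, pe), RR_FIXTURE_DECIMALS)
        hi = round(invert_rr(row.par_ci_upper / 100.0, pe), RR_FIXTURE_DECIMALS)
        estimates.append(
            RelativeRiskEstimate(
                factor=row.factor,
                outcome=row.outcome,
                stratum=row.stratum,
                rr=rr,
                ci_lower=lo,
                ci_upper=hi,
            )
        )
    return estimates


@dataclass(frozen=True)
class ReproductionReport:
    """Outcome of recomputing the reportable published PAR cells."""

    cells: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def all_match(self) -> bool:
        return bool(self.cells["match"].all())

    @property
    def n_mismatches(self) -> int:
        return int((~self.cells["match"]).sum())

    def to_text(self) -> str:
        lines = ["Reproduction of published PAR cells (percent, one decimal)", ""]
        for row in self.cells.itertuples(index=False):
            flag = "ok " if row.match else "MISMATCH"
            lines.append(
                f"{flag}  {row.factor} / {row.outcome} / {row.stratum}: "
                f"printed {row.printed} recomputed {row.recomputed}"
            )
        lines.append("")
        lines.append(
            f"{len(self.cells)} cells recomputed, {self.n_mismatches} mismatch(es); "
            f"{len(self.excluded)} cells excluded (prevalence not printed numerically)."
        )
        return "\n".join(lines)


def reproduce_reportable_cells(
    table: pd.DataFrame | None = None,
    rr_fixtures: list[RelativeRiskEstimate] | None = None,
    prevalences: dict[tuple[str, str], float] | None = None,
) -> ReproductionReport:
    """Recompute every reportable PAR cell and diff against the table.

    A cell is reportable when its prevalence is printed in the study
    text.  Each is recomputed as ``levin_par(pe, rr_fixture)``, rendered
    to one-decimal percent (half-up), and compared to the printed value.
    Mismatches are data in the report, not exceptions.
    """
    if table is None:
        table = load_study_table()
    if prevalences is None:
        prevalences = dict(_PRINTED_PREVALENCES)
    if rr_fixtures is None:
        rr_fixtures = derive_implied_rr_table(table, prevalences)
    rr_by_key = {(e.factor, e.outcome, e.stratum): e for e in rr_fixtures}

    recomputed_rows, excluded_rows = [], []
    for row in table.itertuples(index=False):
        key = (row.factor, row.outcome, row.stratum)
        pe = prevalences.get((row.factor, row.stratum))
        if pe is None or key not in rr_by_key:
            excluded_rows.append(
                {"factor": row.factor, "outcome": row.outcome, "stratum": row.stratum}
            )
            continue
        est = rr_by_key[key]
        printed = f"{row.par_point:.1f}"
        recomputed = format_percent(levin_par(pe, est.rr))
        recomputed_rows.append(
            {
                "factor": row.factor,
                "outcome": row.outcome,
                "stratum": row.stratum,
                "pe": pe,
                "rr_fixture": est.rr,
                "printed": printed,
                "recomputed": recomputed,
                "match": printed == recomputed,
            }
        )
    return ReproductionReport(
        cells=pd.DataFrame(recomputed_rows), excluded=pd.DataFrame(excluded_rows)
    )


def _normalise_minus(text: str) -> str:
    # Published tables use U+2212 for negative PARs; normalise on ingest.
    return text.replace("−", "-")


def write_fixture_files(directory) -> dict[str, str]:
    """Regenerate the delimited fixture files from the printed constants.

    Writes ``prevalence.csv``, ``par_table.csv`` and ``derived_rr.csv``
    (comma-separated, UTF-8, dot decimal, with a provenance column) and
    returns the paths.  Byte-identical on every call: nothing is
    hand-edited downstream of the printed constants.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    prev = pd.DataFrame(
        [
            {"factor": p.factor, "outcome": "", "stratum": p.stratum,
             "value": p.value, "provenance": "printed"}
            for p in load_prevalence_fixture()
        ]
    )
    table = load_study_table().assign(provenance="printed")
    rrs = pd.DataFrame(
        [
            {"factor": e.factor, "outcome": e.outcome, "stratum": e.stratum,
             "value": e.rr, "ci_lower": e.ci_lower, "ci_upper": e.ci_upper,
             "log_se": round(e.log_se, 5), "provenance": "derived"}
            for e in derive_implied_rr_table()
        ]
    )
    paths = {}
    for name, frame in [("prevalence", prev), ("par_table", table), ("derived_rr", rrs)]:
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        paths[name] = str(path)
    return paths


def read_fixture_file(path) -> pd.DataFrame:
    """Read a delimited fixture file, normalising Unicode minus signs."""
    from io import StringIO
    from pathlib import Path

    text = _normalise_minus(Path(path).read_text(encoding="utf-8"))
    return pd.read_csv(StringIO(text))
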