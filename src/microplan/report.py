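"""Grouped coverage summaries, pooled statistics, and campaign resource estimates.

The summary table mirrors the standard microplan reporting layout: one row
per grouping key (country, district, ...) with the facility count, total
covered population, mean and sample standard deviation per facility, and the
min/max. Sub-group rows can be pooled exactly into a combined row from
(n, total, SD) alone — the pooled sample variance is

    s^2 = [ sum_i (n_i - 1) s_i^2  +  sum_i n_i (m_i - m)^2 ] / (N - 1)

with group means m_i = T_i / n_i and grand mean m = T / N. All arithmetic is
done on unrounded values; means and SDs are rounded (half away from zero)
only for display.

Resource estimation converts a target population into doses, vials and
vaccination teams with explicit, minimal assumptions; the other microplan
sections (cold chain, operations, supervision, recording, monitoring) are
emitted as template placeholders only.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConsistencyError, InvalidConfigError
from .grid import StratumKey, write_mask_asc


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (12,406.5 -> 12,407)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class GroupSummary:
    """One summary-table row for a group of facilities.

    ``mean_population`` and ``sd_population`` are display-rounded integers;
    the unrounded values are kept alongside so rows can be pooled without
    accumulating rounding error. ``sd_population`` is the sample SD
    (divisor N-1) and is None for singleton groups.
    """

    group_label: str
    n_facilities: int
    population_total: float
    mean_population: int
    sd_population: int | None
    min_population: float
    max_population: float
    mean_raw: float = field(default=None, repr=False)
    sd_raw: float | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_facilities < 1:
            raise InvalidConfigError("a group summary needs at least one facility")
        if self.mean_raw is None:
            self.mean_raw = self.population_total / self.n_facilities
        if self.sd_raw is None and self.sd_population is not None:
            self.sd_raw = float(self.sd_population)


def summarize_by_group(coverage, facility_groups: dict) -> list[GroupSummary]:
    """Summary rows of per-facility covered population, one per group label.

    Every facility in the coverage result must have a label in
    ``facility_groups``; rows are sorted by label.
    """
    groups: dict[str, list[float]] = {}
    for fc in coverage.per_facility:
        if fc.facility_id not in facility_groups:
            raise ConsistencyError(f"facility {fc.facility_id!r} has no group label")
        groups.setdefault(facility_groups[fc.facility_id], []).append(fc.population_total)
    rows = []
    for label in sorted(groups):
        vals = groups[label]
        n = len(vals)
        total = sum(vals)
        mean = total / n
        if n >= 2:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            sd_raw = math.sqrt(var)
            sd = round_half_away(sd_raw)
        else:
            sd_raw, sd = None, None
        rows.append(GroupSummary(group_label=label, n_facilities=n, population_total=total,
                                 mean_population=round_half_away(mean), sd_population=sd,
                                 min_population=min(vals), max_population=max(vals),
                                 mean_raw=mean, sd_raw=sd_raw))
    return rows


def combine_group_summaries(rows: list[GroupSummary], label: str = "Total") -> GroupSummary:
    """Pool sub-group rows into one combined row.

    Exact on unrounded inputs; singleton rows (n=1, SD missing) contribute
    zero within-group sum of squares. A single row is returned unchanged.
    """
    if not rows:
        raise InvalidConfigError("cannot combine an empty list of group summaries")
    if len(rows) == 1:
        return rows[0]
    N = sum(r.n_facilities for r in rows)
    T = sum(r.population_total for r in rows)
    m = T / N
    ss_within = 0.0
    ss_between = 0.0
    for r in rows:
        mi = r.population_total / r.n_facilities
        si = r.sd_raw if r.sd_raw is not None else 0.0
        ss_within += (r.n_facilities - 1) * si * si
        ss_between += r.n_facilities * (mi - m) ** 2
    sd_raw = math.sqrt((ss_within + ss_between) / (N - 1)) if N >= 2 else None
    return GroupSummary(group_label=label, n_facilities=N, population_total=T,
                        mean_population=round_half_away(m),
                        sd_population=None if sd_raw is None else round_half_away(sd_raw),
                        min_population=min(r.min_population for r in rows),
                        max_population=max(r.max_population for r in rows),
                        mean_raw=m, sd_raw=sd_raw)


# ---------------------------------------------------------------------------
# Resource estimation
# ---------------------------------------------------------------------------

@dataclass
class ResourceAssumptions:
    """Campaign planning assumptions.

    target_strata: which age/sex slices the campaign targets.
    doses_per_person: scheduled doses per targeted person (e.g. 2).
    wastage_fraction: extra doses procured per dose delivered (>= 0).
    vial_doses: doses per vial.
    team_daily_throughput: doses one vaccination team delivers per day.
    campaign_days: planned campaign length in days.
    """

    target_strata: tuple
    doses_per_person: float = 1.0
    wastage_fraction: float = 0.1
    vial_doses: int = 10
    team_daily_throughput: int = 150
    campaign_days: int = 10

    def __post_init__(self):
        if not self.target_strata:
            raise InvalidConfigError("target_strata must not be empty")
        if self.doses_per_person <= 0 or self.vial_doses <= 0 \
                or self.team_daily_throughput <= 0 or self.campaign_days <= 0:
            raise InvalidConfigError("resource assumptions must be positive")
        if self.wastage_fraction < 0:
            raise InvalidConfigError("wastage_fraction must be >= 0")
        self.target_strata = tuple(StratumKey(*k) for k in self.target_strata)


@dataclass
class FacilityResources:
    facility_id: str
    target_population: int
    doses_needed: int
    vials_needed: int
    teams_needed: int


@dataclass
class ResourcePlan:
    per_facility: list
    total_target: int
    total_doses: int
    total_vials: int
    total_teams: int
    #: the non-quantified microplan sections, kept as named placeholders
    sections: tuple = ("resource_estimation", "cold_chain_logistics", "operations",
                       "supervision", "recording_and_reporting", "monitoring_framework")


def estimate_resources(coverage, assumptions: ResourceAssumptions) -> ResourcePlan:
    """Per-facility doses, vials and teams from covered target population.

    doses = ceil(target x doses_per_person);
    vials = ceil(doses x (1 + wastage) / vial_doses);
    teams = ceil(doses / (throughput x days)).
    """
    per = []
    for fc in sorted(coverage.per_facility, key=lambda f: f.facility_id):
        target = sum(fc.population_by_stratum.get(k, 0) for k in assumptions.target_strata)
        target = round_half_away(target)
        doses = math.ceil(target * assumptions.doses_per_person)
        vials = math.ceil(doses * (1 + assumptions.wastage_fraction) / assumptions.vial_doses)
        teams = math.ceil(doses / (assumptions.team_daily_throughput * assumptions.campaign_days))
        per.append(FacilityResources(fc.facility_id, target, doses, vials, teams))
    return ResourcePlan(per_facility=per,
                        total_target=sum(p.target_population for p in per),
                        total_doses=sum(p.doses_needed for p in per),
                        total_vials=sum(p.vials_needed for p in per),
                        total_teams=sum(p.teams_needed for p in per))


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["group", "n_facilities", "total_population", "mean_population",
                  "sd_population", "min_population", "max_population"]


def _fmt_pop(x) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_summary_csv(summaries, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REPORT_COLUMNS)
        for s in summaries:
            w.writerow([s.group_label, s.n_facilities, _fmt_pop(s.population_total),
                        s.mean_population,
                        "" if s.sd_population is None else s.sd_population,
                        _fmt_pop(s.min_population), _fmt_pop(s.max_population)])


def read_summary_csv(path) -> list[GroupSummary]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sd = row["sd_population"]
            out.append(GroupSummary(
                group_label=row["group"], n_facilities=int(row["n_facilities"]),
                population_total=float(row["total_population"]),
                mean_population=int(row["mean_population"]),
                sd_population=None if sd == "" else int(sd),
                min_population=float(row["min_population"]),
                max_population=float(row["max_population"])))
    return out


def write_coverage_csv(coverage, path) -> None:
    strata = sorted({k for fc in coverage.per_facility for k in fc.population_by_stratum})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "assignment", "cutoff_m", "population_total", "n_cells"]
                   + [f"{k.age_band}_{k.sex}" for k in strata])
        for fc in sorted(coverage.per_facility, key=lambda f: f.facility_id):
            w.writerow([fc.facility_id, fc.assignment, _fmt_pop(coverage.cutoff_m),
                        _fmt_pop(fc.population_total), fc.n_cells]
                       + [_fmt_pop(fc.population_by_stratum.get(k, 0)) for k in strata])


def read_coverage_csv(path):
    """Re-read a coverage.csv written by :func:`write_coverage_csv`.

    Returns a minimal :class:`~microplan.coverage.CoverageResult` carrying
    per-facility rows only (no underserved mask), enough for summarizing and
    resource estimation.
    """
    from .coverage import CoverageResult, FacilityCoverage

    per = []
    cutoff = float("nan")
    assignment = ""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fixed = {"facility_id", "assignment", "cutoff_m", "population_total", "n_cells"}
        strata_cols = [c for c in reader.fieldnames if c not in fixed]
        for row in reader:
            assignment = row["assignment"]
            cutoff = float(row["cutoff_m"])
            by = {}
            for col in strata_cols:
                band, sex = col.rsplit("_", 1)
                by[StratumKey(band, sex)] = float(row[col])
            per.append(FacilityCoverage(
                facility_id=row["facility_id"], population_total=float(row["population_total"]),
                population_by_stratum=by, n_cells=int(row["n_cells"]), assignment=assignment))
    import numpy as np
    return CoverageResult(per_facility=per, underserved_total=0, underserved_by_stratum={},
                          underserved_mask=np.zeros((1, 1), dtype=bool),
                          assignment=assignment or "independent", cutoff_m=cutoff, mode="")


def write_resources_csv(plan: ResourcePlan, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "target_population", "doses_needed",
                    "vials_needed", "teams_needed"])
        for p in plan.per_facility:
            w.writerow([p.facility_id, p.target_population, p.doses_needed,
                        p.vials_needed, p.teams_needed])
        w.writerow(["TOTAL", plan.total_target, plan.total_doses,
                    plan.total_vials, plan.total_teams])


def write_rates_csv(rates, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "cases", "population", "rate", "rate_basis"])
        for fid in sorted(rates.per_facility):
            rec = rates.per_facility[fid]
            w.writerow([fid, rec["case_count"], _fmt_pop(rec["population_total"]),
                        "" if rec["rate"] is None else repr(rec["rate"]),
                        _fmt_pop(rates.rate_basis)])


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(summaries, coverage, plan, out_dir, grid=None, catchments=None,
                 config: dict | None = None, input_files=None) -> dict:
    """Write the full report bundle and a run manifest; idempotent.

    Emits report.csv, coverage.csv, resources.csv, and when the inputs are
    provided catchments.geojson and underserved.asc, plus manifest.json
    echoing the configuration and hashing the input files.
    """
    from .catchment import catchments_to_geojson

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_summary_csv(summaries, out_dir / "report.csv")
    write_coverage_csv(coverage, out_dir / "coverage.csv")
    write_resources_csv(plan, out_dir / "resources.csv")
    written = ["report.csv", "coverage.csv", "resources.csv"]
    if catchments is not None:
        catchments_to_geojson(catchments, out_dir / "catchments.geojson")
        written.append("catchments.geojson")
    if grid is not None:
        write_mask_asc(out_dir / "underserved.asc", grid, coverage.underserved_mask)
        written.append("underserved.asc")
    manifest = {
        "config": config or {},
        "outputs": written,
        "input_hashes": {str(p): _file_sha256(p) for p in (input_files or [])},
        "assignment": coverage.assignment,
        "cutoff_m": coverage.cutoff_m,
        "mode": coverage.mode,
        "rule": coverage.rule,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
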