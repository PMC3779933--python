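"""Pooled plate-assay screening: design, hit calling, deconvolution, tallies.

The screening workflow pools 16 source microtiter plates (95 clones + 1
negative-control well each) onto one 96-well assay plate, so each assay well
holds 16 clones.  Wells whose absorbance or fluorescence signal exceeds the
plate mean by more than ``sd_multiplier`` standard deviations (default 2,
computed over all wells of that plate) are designated positive; clones pooled
into positive wells are expanded onto fresh plates and screened individually
to confirm the activity and identify the responsible clone.  Repeating the
pooling eight times per day allows 16 * 95 * 8 = 12,160 clones to be screened
in parallel against the full substrate panel.

Readings are tidy DataFrames with columns
``plate_id, well, substrate, timepoint, modality, value`` (wells ``A1``..``H12``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DataError,
    InsufficientDataError,
    InvalidParameterError,
)
from .panel import MODALITY_VISUAL, load_substrate_panel

ROWS = "ABCDEFGH"
COLS = range(1, 13)
#: All 96 wells in row-major order: A1..A12, B1..B12, ..., H12.
WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in ROWS for c in COLS)
#: Well reserved for the negative control on every source plate.
CONTROL_WELL = "H12"
#: The 95 wells that receive clones on a source plate.
CLONE_WELLS: tuple[str, ...] = tuple(w for w in WELLS if w != CONTROL_WELL)

READING_COLUMNS = ["plate_id", "well", "substrate", "timepoint", "modality", "value"]
TIMEPOINTS_DEFAULT = ("24h", "5d")


# ---------------------------------------------------------------------------
# Pooling design
# ---------------------------------------------------------------------------


@dataclass
class PoolingDesign:
    """Static layout mapping every clone to a source well and an assay well.

    ``assignments`` has one row per clone with columns
    ``clone_id, source_plate, source_well, assay_plate, assay_well``.
    ``n_substrates`` is the assay-accounting substrate count used for design
    arithmetic (reactions per day, total assays).
    """

    assignments: pd.DataFrame
    plates_per_pool: int = 16
    wells_per_plate: int = 96
    clones_per_plate: int = 95
    rounds_per_day: int = 8
    n_substrates: int = 14
    control_well: str = CONTROL_WELL

    def __post_init__(self) -> None:
        if self.plates_per_pool < 1 or self.clones_per_plate < 1:
            raise InvalidParameterError("pool factor and plate capacity must be >= 1")
        if self.clones_per_plate >= self.wells_per_plate:
            raise InvalidParameterError(
                "clones_per_plate must leave room for the control well"
            )
        counts = self.assignments.groupby(["assay_plate", "assay_well"]).size()
        if (counts > self.plates_per_pool).any():
            raise InvalidParameterError("an assay well holds more than plates_per_pool clones")
        if self.assignments["clone_id"].duplicated().any():
            raise InvalidParameterError("each clone must map to exactly one assay well")

    @property
    def n_clones(self) -> int:
        return len(self.assignments)

    @property
    def n_assay_plates(self) -> int:
        return self.assignments["assay_plate"].nunique()

    def clones_in_well(self, assay_plate: str, assay_well: str) -> list[str]:
        sel = (self.assignments["assay_plate"] == assay_plate) & (
            self.assignments["assay_well"] == assay_well
        )
        return self.assignments.loc[sel, "clone_id"].tolist()


def build_pooling_design(
    n_clones: int,
    clone_ids: Optional[Sequence[str]] = None,
    plates_per_pool: int = 16,
    clones_per_plate: int = 95,
    rounds_per_day: int = 8,
    n_substrates: int = 14,
) -> PoolingDesign:
    """Lay clones onto source plates and pool them onto assay plates.

    Clones fill source plates in plate-major, row-major well order (95 per
    plate, ``H12`` left as negative control); source plate ``i`` pools onto
    assay plate ``i // plates_per_pool``, well position preserved, so each
    assay well collects up to ``plates_per_pool`` clones.  The layout is
    deterministic.  With ``plates_per_pool=1`` the mapping is the identity.
    """
    if n_clones < 1:
        raise InvalidParameterError("n_clones must be >= 1")
    if clone_ids is None:
        width = max(5, len(str(n_clones)))
        clone_ids = [f"clone_{i:0{width}d}" for i in range(n_clones)]
    elif len(clone_ids) != n_clones:
        raise InvalidParameterError("clone_ids length must equal n_clones")

    clone_wells = [w for w in WELLS if w != CONTROL_WELL][:clones_per_plate]
    idx = np.arange(n_clones)
    src_plate = idx // clones_per_plate
    src_well = [clone_wells[i % clones_per_plate] for i in idx]
    assay_plate = src_plate // plates_per_pool
    assignments = pd.DataFrame(
        {
            "clone_id": list(clone_ids),
            "source_plate": [f"SP{p:04d}" for p in src_plate],
            "source_well": src_well,
            "assay_plate": [f"AP{p:04d}" for p in assay_plate],
            "assay_well": src_well,
        }
    )
    return PoolingDesign(
        assignments=assignments,
        plates_per_pool=plates_per_pool,
        clones_per_plate=clones_per_plate,
        rounds_per_day=rounds_per_day,
        n_substrates=n_substrates,
    )


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------


@dataclass
class HitCallingParams:
    """Parameters of the plate-level positivity rule.

    ``sd_multiplier``: threshold is mean + sd_multiplier * SD over all wells
    of the plate (controls included).  ``combine_timepoints``: "any" calls a
    well positive if it exceeds the threshold at any timepoint; "all"
    requires every timepoint; a timepoint label restricts to that timepoint.
    ``strict``: use strict inequality (value > threshold).  ``population_sd``
    selects the n-denominator standard deviation (the plate's wells are the
    whole population under test); set False for the n-1 sample flavour.
    ``near_threshold_margin``: positives within this relative margin of the
    threshold are flagged as near-threshold (borderline) calls.
    """

    sd_multiplier: float = 2.0
    combine_timepoints: str = "any"
    strict: bool = True
    population_sd: bool = True
    near_threshold_margin: float = 0.10

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise InvalidParameterError("sd_multiplier must be > 0")
        if self.near_threshold_margin < 0:
            raise InvalidParameterError("near_threshold_margin must be >= 0")


@dataclass
class HitCalls:
    """Result of hit calling: per-well calls and the thresholds applied.

    ``wells``: one row per (plate_id, well, substrate) with boolean
    ``positive`` and ``near_threshold`` columns.
    ``thresholds``: one row per (plate_id, substrate, timepoint) with the
    plate mean, SD and threshold used (visual groups carry NaN).
    """

    wells: pd.DataFrame
    thresholds: pd.DataFrame

    def positive_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["positive"]].reset_index(drop=True)


def _validate_readings(readings: pd.DataFrame) -> pd.DataFrame:
    missing = set(READING_COLUMNS) - set(readings.columns)
    if missing:
        raise DataError(f"readings missing columns: {sorted(missing)}")
    if readings.duplicated(["plate_id", "well", "substrate", "timepoint"]).any():
        raise DataError("duplicate (plate, well, substrate, timepoint) readings")
    if not np.isfinite(readings["value"].to_numpy(dtype=float)).all():
        raise DataError("non-finite reading values")
    return readings


def call_hits(readings: pd.DataFrame, params: HitCallingParams | None = None) -> HitCalls:
    """Apply the plate-wise mean + k*SD rule to a set of readings.

    Thresholds are computed per (plate, substrate, timepoint) over **all**
    wells present for that group, negative controls included.  Visual
    (binary) readings bypass the threshold: any nonzero value is positive.
    """
    params = params or HitCallingParams()
    readings = _validate_readings(readings)

    thresh_rows = []
    per_tp = []
    for (plate, substrate, tp), grp in readings.groupby(
        ["plate_id", "substrate", "timepoint"], sort=True
    ):
        modality = grp["modality"].iloc[0]
        values = grp["value"].to_numpy(dtype=float)
        if modality == MODALITY_VISUAL:
            pos = values > 0
            thresh_rows.append((plate, substrate, tp, np.nan, np.nan, np.nan))
            near = np.zeros_like(pos)
        else:
            if len(values) < 2:
                raise InsufficientDataError(
                    f"need >= 2 wells to compute a threshold for {plate}/{substrate}/{tp}"
                )
            mean = values.mean()
            sd = values.std(ddof=0 if params.population_sd else 1)
            threshold = mean + params.sd_multiplier * sd
            pos = values > threshold if params.strict else values >= threshold
            near = pos & (values <= threshold * (1.0 + params.near_threshold_margin))
            thresh_rows.append((plate, substrate, tp, mean, sd, threshold))
        per_tp.append(
            pd.DataFrame(
                {
                    "plate_id": plate,
                    "well": grp["well"].to_numpy(),
                    "substrate": substrate,
                    "timepoint": tp,
                    "positive": pos,
                    "near_threshold": near,
                }
            )
        )

    thresholds = pd.DataFrame(
        thresh_rows,
        columns=["plate_id", "substrate", "timepoint", "mean", "sd", "threshold"],
    )
    calls_tp = pd.concat(per_tp, ignore_index=True)

    rule = params.combine_timepoints
    if rule not in ("any", "all") and rule not in set(calls_tp["timepoint"]):
        raise InvalidParameterError(f"unknown combine_timepoints rule {rule!r}")
    if rule not in ("any", "all"):
        calls_tp = calls_tp[calls_tp["timepoint"] == rule]
    agg = "any" if rule != "all" else "all"
    wells = (
        calls_tp.groupby(["plate_id", "well", "substrate"], sort=True)
        .agg(positive=("positive", agg), near_threshold=("near_threshold", "any"))
        .reset_index()
    )
    # a call is near-threshold only if it is positive and every firing
    # timepoint was within the margin
    firing_near = (
        calls_tp[calls_tp["positive"]]
        .groupby(["plate_id", "well", "substrate"])["near_threshold"]
        .all()
        .rename("near_all")
    )
    wells = wells.merge(firing_near, on=["plate_id", "well", "substrate"], how="left")
    wells["near_threshold"] = wells["positive"] & wells["near_all"].eq(True)
    wells = wells.drop(columns="near_all")
    return HitCalls(wells=wells, thresholds=thresholds)


# ---------------------------------------------------------------------------
# Deconvolution and confirmation
# ---------------------------------------------------------------------------


def deconvolve(hits: HitCalls, design: PoolingDesign) -> pd.DataFrame:
    """Expand positive pooled wells to the clones they contain.

    Returns one row per candidate clone with columns
    ``clone_id, substrates`` (sorted tuple of the substrates whose assays
    fired for the clone's pooled well) plus the pooled well address.  Each
    clone appears at most once; substrate tags are unioned across assays.
    """
    positives = hits.positive_wells()
    if positives.empty:
        return pd.DataFrame(columns=["clone_id", "assay_plate", "assay_well", "substrates"])
    keyed = design.assignments.set_index(["assay_plate", "assay_well"]).sort_index()
    records: dict[str, dict] = {}
    for _, row in positives.iterrows():
        key = (row["plate_id"], row["well"])
        if key not in keyed.index:
            if row["well"] == design.control_well:
                continue  # clone-free negative control fired: nothing to expand
            raise ConsistencyError(
                f"positive well {key} has no clones in the pooling design"
            )
        members = keyed.loc[[key]]
        for clone_id in members["clone_id"]:
            rec = records.setdefault(
                clone_id,
                {"clone_id": clone_id, "assay_plate": key[0], "assay_well": key[1],
                 "substrates": set()},
            )
            rec["substrates"].add(row["substrate"])
    if not records:
        return pd.DataFrame(columns=["clone_id", "assay_plate", "assay_well", "substrates"])
    out = pd.DataFrame(records.values())
    out["substrates"] = out["substrates"].map(lambda s: tuple(sorted(s)))
    return out.sort_values("clone_id", ignore_index=True)


@dataclass
class ActivityProfile:
    """Per-clone confirmed substrate activities.

    ``activities`` maps clone_id -> frozenset of substrates with confirmed
    activity (clones screened but negative map to the empty set).
    ``near_threshold`` lists (clone_id, substrate) calls that sat within the
    borderline margin of the threshold.
    """

    activities: dict[str, frozenset[str]] = field(default_factory=dict)
    near_threshold: list[tuple[str, str]] = field(default_factory=list)

    def positive_clones(self) -> list[str]:
        return sorted(c for c, s in self.activities.items() if s)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clone_id": c, "substrate": s}
            for c, subs in sorted(self.activities.items())
            for s in sorted(subs)
        ]
        return pd.DataFrame(rows, columns=["clone_id", "substrate"])


def confirm_clones(
    individual_readings: pd.DataFrame,
    layout: pd.DataFrame,
    params: HitCallingParams | None = None,
    rescreen_readings: pd.DataFrame | None = None,
    candidate_substrates: Mapping[str, Iterable[str]] | None = None,
) -> ActivityProfile:
    """Call hits on expansion plates carrying one clone per well.

    ``layout`` maps (plate_id, well) -> clone_id for the expansion plates.
    The same threshold rule as the pooled phase is applied; a clone is
    confirmed for a substrate iff its well is positive.  Borderline calls
    (within the near-threshold margin) are only confirmed if they are
    positive again in ``rescreen_readings`` when a re-screen is supplied;
    without one they stay confirmed but flagged.  When
    ``candidate_substrates`` (from :func:`deconvolve`) is given, a clone can
    only confirm the activities its pooled well was detected on — the
    expansion exists to confirm the detected activity, not to re-screen the
    panel de novo.
    """
    params = params or HitCallingParams()
    if layout.duplicated(["plate_id", "well"]).any():
        raise ConsistencyError("expansion layout assigns two clones to one well")
    hits = call_hits(individual_readings, params)
    calls = hits.wells.merge(layout, on=["plate_id", "well"], how="left")
    calls = calls[calls["clone_id"].notna()]

    rescreen_pos: set[tuple[str, str]] | None = None
    if rescreen_readings is not None:
        re_hits = call_hits(rescreen_readings, params)
        re_calls = re_hits.wells.merge(layout, on=["plate_id", "well"], how="left")
        re_calls = re_calls[re_calls["clone_id"].notna() & re_calls["positive"]]
        rescreen_pos = set(zip(re_calls["clone_id"], re_calls["substrate"]))

    profile = ActivityProfile(
        activities={c: frozenset() for c in layout["clone_id"].dropna()}
    )
    confirmed: dict[str, set[str]] = {c: set() for c in profile.activities}
    allowed = (
        {c: set(s) for c, s in candidate_substrates.items()}
        if candidate_substrates is not None
        else None
    )
    for _, row in calls[calls["positive"]].iterrows():
        clone, substrate = row["clone_id"], row["substrate"]
        if allowed is not None and substrate not in allowed.get(clone, set()):
            continue
        if row["near_threshold"]:
            profile.near_threshold.append((clone, substrate))
            if rescreen_pos is not None and (clone, substrate) not in rescreen_pos:
                continue  # borderline call failed to reproduce
        confirmed[clone].add(substrate)
    profile.activities = {c: frozenset(s) for c, s in confirmed.items()}
    return profile


def determine_lod(
    dilution_series: Sequence[tuple[float, float]], background: float
) -> Optional[float]:
    """Lowest concentration whose signal exceeds the negative-control background.

    ``dilution_series`` must be sorted ascending by concentration. Returns
    None when no point rises above background.
    """
    if len(dilution_series) == 0:
        raise InvalidParameterError("dilution series is empty")
    concs = [c for c, _ in dilution_series]
    if any(b < a for a, b in zip(concs, concs[1:])):
        raise InvalidParameterError("dilution series must be sorted by concentration")
    for conc, value in dilution_series:
        if value > background:
            return conc
    return None


# ---------------------------------------------------------------------------
# Screen-level tallies
# ---------------------------------------------------------------------------


@dataclass
class ScreenSummary:
    """Campaign-level accounting of a screen."""

    n_clones_screened: int
    n_substrates: int
    n_assays: int
    n_positive_assays: int
    n_unique_positive_clones: Optional[int]
    n_multi_substrate_clones: Optional[int]
    per_substrate_positive_frequency: dict[str, float]
    average_positive_rate: Optional[float]
    n_clones_observed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"substrate": s, "positive_frequency_pct": f}
            for s, f in self.per_substrate_positive_frequency.items()
        ]
        return pd.DataFrame(rows)


def tally(
    profiles: ActivityProfile | Mapping[str, Iterable[str]],
    n_clones_screened: int,
    panel: pd.DataFrame | None = None,
    n_substrates: int = 14,
) -> ScreenSummary:
    """Summarise confirmed activity profiles into campaign statistics.

    ``n_clones_screened`` is the operator-supplied denominator; when it
    disagrees with the number of distinct clones observed, both are reported
    (``n_clones_observed``).  Frequencies are percentages of the denominator.
    """
    acts = profiles.activities if isinstance(profiles, ActivityProfile) else dict(profiles)
    panel = panel if panel is not None else load_substrate_panel()
    valid = set(panel["substrate"])
    for clone, subs in acts.items():
        unknown = set(subs) - valid
        if unknown:
            raise ConsistencyError(f"clone {clone} reports unknown substrates {unknown}")
    n_observed = len(acts)
    if n_clones_screened < n_observed:
        raise ConsistencyError(
            f"denominator {n_clones_screened} < {n_observed} distinct clones observed"
        )
    per_clone = {c: len(set(s)) for c, s in acts.items()}
    n_positive_assays = sum(per_clone.values())
    n_unique = sum(1 for v in per_clone.values() if v >= 1)
    n_multi = sum(1 for v in per_clone.values() if v >= 2)
    freq = {}
    for substrate in panel["substrate"]:
        k = sum(1 for s in acts.values() if substrate in s)
        freq[substrate] = 100.0 * k / n_clones_screened
    return ScreenSummary(
        n_clones_screened=n_clones_screened,
        n_substrates=n_substrates,
        n_assays=n_clones_screened * n_substrates,
        n_positive_assays=n_positive_assays,
        n_unique_positive_clones=n_unique,
        n_multi_substrate_clones=n_multi,
        per_substrate_positive_frequency=freq,
        average_positive_rate=100.0 * n_unique / n_clones_screened,
        n_clones_observed=n_observed if n_observed != n_clones_screened else None,
    )


def summarize_counts(
    counts: pd.DataFrame,
    n_clones_screened: int,
    n_unique_clones: Optional[int] = None,
    n_substrates: int = 14,
) -> ScreenSummary:
    """Tally arithmetic on a printed substrate x library positive-count table.

    Positive assays are the grand total of the counts; per-substrate
    frequencies divide row sums by the operator denominator.  Unique-clone
    statistics cannot be derived from counts alone, so the published unique
    count may be supplied to compute the average positive rate.
    """
    if (counts.to_numpy() < 0).any():
        raise DataError("negative counts")
    row_sums = counts.sum(axis=1)
    freq = {s: 100.0 * int(k) / n_clones_screened for s, k in row_sums.items()}
    n_pos = int(row_sums.sum())
    return ScreenSummary(
        n_clones_screened=n_clones_screened,
        n_substrates=n_substrates,
        n_assays=n_clones_screened * n_substrates,
        n_positive_assays=n_pos,
        n_unique_positive_clones=n_unique_clones,
        n_multi_substrate_clones=None,
        per_substrate_positive_frequency=freq,
        average_positive_rate=(
            100.0 * n_unique_clones / n_clones_screened if n_unique_clones else None
        ),
    )
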