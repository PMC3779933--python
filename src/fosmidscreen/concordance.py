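"""Predicted-versus-confirmed activity concordance.

Per-ORF family annotations are filtered (e-value cut-off, best hit per ORF),
mapped to assayable substrates through the family -> substrate relation, and
compared with the biochemically confirmed activity profile.  Every
clone x substrate pair lands in exactly one of four states:

========== ======================= =========================
predicted   confirmed               state
========== ======================= =========================
yes         yes                     ``both``
yes         no                      ``predicted_only``
no          yes                     ``confirmed_only``
no          no                      ``neither``
========== ======================= =========================

A substrate is *fully concordant* when it has no one-sided states; the
confirmed-given-predicted proportion both/(both + predicted_only) measures
how often an in-silico prediction is biochemically borne out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataError, InvalidParameterError

logger = logging.getLogger(__name__)

STATES = ("neither", "predicted_only", "confirmed_only", "both")


@dataclass
class AnnotationFilter:
    """E-value threshold (default 0.1) and best-hit-per-ORF selection."""

    evalue_threshold: float = 0.1
    best_hit_only: bool = True

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise InvalidParameterError("evalue_threshold must be > 0")


def filter_annotations(
    table: pd.DataFrame, filt: AnnotationFilter | None = None
) -> pd.DataFrame:
    """Drop records above the e-value threshold; keep the lowest-e-value
    record per ORF when ``best_hit_only``.

    Best-hit selection applies per ORF, not per clone, so one clone keeps
    families across several ORFs.
    """
    filt = filt or AnnotationFilter()
    if table.empty:
        return table.copy()
    if (table["evalue"] < 0).any():
        raise DataError("negative e-values")
    kept = table[table["evalue"] <= filt.evalue_threshold].copy()
    if filt.best_hit_only and not kept.empty:
        kept = kept.sort_values(
            ["clone_id", "orf_id", "evalue"], kind="stable"
        ).groupby(["clone_id", "orf_id"], as_index=False).first()
    return kept.reset_index(drop=True)


def predict_activities(
    table: pd.DataFrame,
    family_map: Mapping[str, Iterable[str]],
    clone_ids: Sequence[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Union of mapped substrates over each clone's (filtered) families.

    Families absent from the map contribute nothing and are logged; families
    mapped to the empty set (e.g. CBMs) are recognised but predict nothing.
    ``clone_ids`` optionally fixes the clone universe so annotation-free
    clones appear with empty predictions.
    """
    predictions: dict[str, set[str]] = {c: set() for c in (clone_ids or [])}
    unmapped: set[str] = set()
    for _, row in table.iterrows():
        fam = row["family"]
        predictions.setdefault(row["clone_id"], set())
        if fam not in family_map:
            unmapped.add(fam)
            continue
        predictions[row["clone_id"]].update(family_map[fam])
    if unmapped:
        logger.warning("families absent from substrate map ignored: %s", sorted(unmapped))
    return {c: frozenset(s) for c, s in predictions.items()}


def classify_concordance(
    predicted: Mapping[str, Iterable[str]],
    confirmed: Mapping[str, Iterable[str]],
    substrates: Sequence[str],
) -> pd.DataFrame:
    """Four-state clone x substrate classification.

    Both profiles must cover the same clone universe.  Returns a DataFrame
    indexed by clone_id with one column per substrate holding a state string.
    """
    if set(predicted) != set(confirmed):
        only_p = set(predicted) - set(confirmed)
        only_c = set(confirmed) - set(predicted)
        raise ConsistencyError(
            f"clone universes differ (predicted-only: {sorted(only_p)[:3]}, "
            f"confirmed-only: {sorted(only_c)[:3]})"
        )
    clones = sorted(predicted)
    data = {}
    for substrate in substrates:
        col = []
        for clone in clones:
            p = substrate in predicted[clone]
            c = substrate in confirmed[clone]
            col.append(
                "both" if p and c
                else "predicted_only" if p
                else "confirmed_only" if c
                else "neither"
            )
        data[substrate] = col
    return pd.DataFrame(data, index=pd.Index(clones, name="clone_id"))


def summarize_concordance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-substrate state counts and derived proportions.

    ``confirmed_given_predicted`` is both/(both + predicted_only), NaN
    (undefined) when nothing was predicted; ``fully_concordant`` is True when
    the substrate has no one-sided state.
    """
    if matrix.empty:
        raise InvalidParameterError("empty concordance matrix")
    rows = []
    for substrate in matrix.columns:
        counts = matrix[substrate].value_counts()
        both = int(counts.get("both", 0))
        pred_only = int(counts.get("predicted_only", 0))
        conf_only = int(counts.get("confirmed_only", 0))
        neither = int(counts.get("neither", 0))
        denom = both + pred_only
        rows.append(
            {
                "substrate": substrate,
                "both": both,
                "predicted_only": pred_only,
                "confirmed_only": conf_only,
                "neither": neither,
                "confirmed_given_predicted": (both / denom if denom else np.nan),
                "unpredicted_confirmed": conf_only,
                "fully_concordant": pred_only == 0 and conf_only == 0,
            }
        )
    return pd.DataFrame(rows).set_index("substrate")


def bin_trait_table(
    assignments: pd.DataFrame, matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group the concordance matrix by genome bin.

    ``assignments`` is the clone -> bin table from the binning module;
    clones missing from it fall into bin 0.  Returns ``(table, counts)``:
    *table* is the concordance matrix re-indexed by (bin, clone_id);
    *counts* tallies, per bin and substrate, the number of clones in each
    non-``neither`` state.
    """
    bin_of = dict(zip(assignments["clone_id"], assignments["bin"]))
    bins = [int(bin_of.get(c, 0)) for c in matrix.index]
    table = matrix.copy()
    table.index = pd.MultiIndex.from_arrays(
        [bins, matrix.index], names=["bin", "clone_id"]
    )
    table = table.sort_index()
    rows = []
    for b, grp in table.groupby(level="bin"):
        for substrate in matrix.columns:
            counts = grp[substrate].value_counts()
            rows.append(
                {
                    "bin": int(b),
                    "substrate": substrate,
                    "both": int(counts.get("both", 0)),
                    "predicted_only": int(counts.get("predicted_only", 0)),
                    "confirmed_only": int(counts.get("confirmed_only", 0)),
                    "confirmed": int(counts.get("both", 0))
                    + int(counts.get("confirmed_only", 0)),
                }
            )
    return table, pd.DataFrame(rows)
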