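"""Substrate panel and enzyme-family -> substrate relation.

The screening panel couples 11 liquid-culture chromogenic/fluorogenic
carbohydrate and oxidative substrates with two solid-media (visual readout)
assays for phosphatase and protease activity.  Per-substrate detection
modality drives downstream hit calling: plate-reader modalities (absorbance,
fluorescence) go through the mean + k*SD threshold rule, visual modalities
are binary.

The family -> substrate map encodes which assayable substrates an annotated
glycoside-hydrolase family (or phosphatase/peptidase domain) is expected to
act on; it ships as an editable two-column TSV because the relation is
curated knowledge, not code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import DataError

MODALITY_ABSORBANCE = "absorbance"
MODALITY_FLUORESCENCE = "fluorescence"
MODALITY_VISUAL = "visual"


def _data_path(name: str):
    return resources.files("fosmidscreen.data").joinpath(name)


def detection_modality(detection: str) -> str:
    """Map a panel 'detection' entry to a readout modality.

    Excitation/emission pairs (e.g. '365/450') are fluorescence, a single
    wavelength is absorbance, and 'visual' stays visual.
    """
    d = str(detection).strip().lower()
    if d == "visual":
        return MODALITY_VISUAL
    if "/" in d:
        return MODALITY_FLUORESCENCE
    return MODALITY_ABSORBANCE


def load_substrate_panel(path=None) -> pd.DataFrame:
    """Load the substrate panel (default: the packaged 13-substrate panel).

    Returns a DataFrame with columns substrate, enzyme, function,
    concentration, detection, assay_type and a derived ``modality`` column.
    """
    src = path if path is not None else _data_path("substrate_panel.tsv")
    panel = pd.read_csv(src, sep="\t", comment="#")
    required = {"substrate", "detection", "assay_type"}
    missing = required - set(panel.columns)
    if missing:
        raise DataError(f"substrate panel missing columns: {sorted(missing)}")
    if panel["substrate"].duplicated().any():
        raise DataError("substrate names must be unique")
    panel["modality"] = panel["detection"].map(detection_modality)
    solid_visual = panel.loc[panel["assay_type"] == "solid", "modality"]
    if not (solid_visual == MODALITY_VISUAL).all():
        raise DataError("solid assays must use visual detection")
    return panel


def load_family_substrate_map(path=None) -> dict[str, frozenset[str]]:
    """Load the family -> substrates relation as ``{family: {substrate, ...}}``.

    Families listed with no substrates (e.g. carbohydrate-binding modules)
    map to the empty set: they are recognised but predict no activity.
    """
    src = path if path is not None else _data_path("family_substrate_map.tsv")
    with (open(src) if isinstance(src, str) else src.open()) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    mapping: dict[str, frozenset[str]] = {}
    for line in lines:
        parts = line.split("\t")
        family = parts[0].strip()
        if family == "family":  # header
            continue
        if family in mapping:
            raise DataError(f"duplicate family {family!r} in map")
        subs = parts[1] if len(parts) > 1 else ""
        mapping[family] = frozenset(s.strip() for s in subs.split(",") if s.strip())
    return mapping


def load_screen_counts(path=None):
    """Load the packaged published screen tallies.

    Returns ``(counts, library_sizes, reported)`` where *counts* is a
    substrate x library DataFrame of positive-assay counts, *library_sizes*
    a Series of clones screened per library, and *reported* a dict of
    campaign-level scalars parsed from the file header
    (``n_clones_screened``, ``n_unique_clones``).
    """
    src = path if path is not None else _data_path("leaf_litter_screen_counts.tsv")
    reported: dict[str, int] = {}
    with (open(src) if isinstance(src, str) else src.open()) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("# reported_"):
            key, _, val = line[len("# reported_"):].partition("=")
            reported[key.strip()] = int(val)
    from io import StringIO

    table = pd.read_csv(StringIO(text), sep="\t", comment="#", index_col=0)
    library_sizes = table.loc["n_clones"].astype(int)
    counts = table.drop(index="n_clones").astype(int)
    return counts, library_sizes, reported
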