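"""Synthetic genomes, fosmid libraries, annotations and plate readings.

This module manufactures inputs with the statistical structure the analysis
chain assumes, together with full ground truth, so every downstream step can
be tested against known answers:

* **Genomes** are drawn from per-taxon Markov chains over {A,C,G,T} (order 3
  by default).  Distinct transition weights give each taxon a distinct
  tetranucleotide signature, which is exactly the compositional structure the
  ESOM binning exploits.
* **Fosmid clones** carry 36-48 kb inserts sampled uniformly from a taxon
  genome, with 0-3 planted enzyme-family genes whose substrate activities
  follow the family -> substrate map.
* **Plate readings** follow an additive signal model: background + host
  background + the sum of active-clone contributions + Gaussian noise,
  clipped at zero.  A nonzero host background models a wild-type expression
  host with interfering endogenous activities; zero models the multi-knockout
  host.  Solid-media (visual) assays yield binary readings.
* **Annotation tables** emulate per-ORF HMM search output (family, e-value)
  with configurable false-negative and false-positive rates; true hits draw
  e-values log-uniformly from [1e-30, 1e-2], spurious ones from [1e-3, 1] so
  both sides of the conventional 0.1 e-value cut-off are exercised.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, InvalidParameterError
from .panel import MODALITY_VISUAL, load_substrate_panel
from .screening import (
    CLONE_WELLS,
    CONTROL_WELL,
    TIMEPOINTS_DEFAULT,
    WELLS,
    PoolingDesign,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Taxon models and genome generation
# ---------------------------------------------------------------------------


@dataclass
class TaxonModel:
    """Markov-chain sequence model giving a taxon its compositional signature.

    ``transition_weights`` has shape (4**order, 4): row c holds the
    next-base weights after the length-``order`` context with code c
    (contexts encoded base-4 with A=0, C=1, G=2, T=3, most significant base
    first).  Rows are normalised to sum to 1 on construction.
    """

    taxon_id: str
    order: int = 3
    transition_weights: Optional[np.ndarray] = None
    gc_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.order < 0:
            raise InvalidParameterError("Markov order must be >= 0")
        n_ctx = 4**self.order
        if self.transition_weights is None:
            self.transition_weights = np.full((n_ctx, 4), 0.25)
        w = np.asarray(self.transition_weights, dtype=float)
        if w.shape != (n_ctx, 4):
            raise InvalidParameterError(
                f"transition_weights must have shape ({n_ctx}, 4), got {w.shape}"
            )
        if (w < 0).any():
            raise InvalidParameterError("transition weights must be non-negative")
        sums = w.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise InvalidParameterError("every context needs a positive total weight")
        self.transition_weights = w / sums

    @classmethod
    def random(
        cls,
        taxon_id: str,
        seed,
        order: int = 3,
        concentration: float = 1.0,
        gc_target: Optional[float] = None,
    ) -> "TaxonModel":
        """Draw a random model with Dirichlet(concentration) context rows.

        An optional ``gc_target`` exponentially tilts every row toward the
        requested G+C fraction before normalisation.
        """
        rng = _as_rng(seed)
        w = rng.dirichlet([concentration] * 4, size=4**order)
        if gc_target is not None:
            if not 0 < gc_target < 1:
                raise InvalidParameterError("gc_target must be in (0, 1)")
            tilt = np.array(
                [1 - gc_target, gc_target, gc_target, 1 - gc_target]
            ) / 0.5
            w = w * tilt
        return cls(taxon_id=taxon_id, order=order, transition_weights=w, gc_target=gc_target)


def random_taxon_models(
    n_taxa: int, seed, order: int = 3, concentration: float = 1.0
) -> list[TaxonModel]:
    """Independent random taxon models ``taxon_00 .. taxon_{n-1}``."""
    rng = _as_rng(seed)
    return [
        TaxonModel.random(f"taxon_{i:02d}", rng, order=order, concentration=concentration)
        for i in range(n_taxa)
    ]


def generate_genome(model: TaxonModel, length: int, seed) -> str:
    """Simulate a genome of exactly ``length`` bases from the taxon model.

    The first ``order`` bases are uniform; subsequent bases follow the
    context-conditional weights. Deterministic for a fixed seed.
    """
    if length < model.order + 1:
        raise InvalidParameterError(
            f"length must be >= order + 1 = {model.order + 1}, got {length}"
        )
    rng = _as_rng(seed)
    order = model.order
    n_ctx = 4**order
    cum = np.cumsum(model.transition_weights, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    cum_rows = [tuple(row) for row in cum]

    out = np.empty(length, dtype=np.uint8)
    start = rng.integers(0, 4, size=order)
    out[:order] = start
    ctx = 0
    for b in start:
        ctx = ctx * 4 + int(b)
    u = rng.random(length - order)
    mod = n_ctx if order > 0 else 1
    for i in range(order, length):
        row = cum_rows[ctx]
        r = u[i - order]
        if r < row[0]:
            b = 0
        elif r < row[1]:
            b = 1
        elif r < row[2]:
            b = 2
        else:
            b = 3
        out[i] = b
        if order > 0:
            ctx = (ctx * 4 + b) % mod
    return "".join(BASES[b] for b in out)


def sample_insert(genome: str, size_range: tuple[int, int], seed) -> tuple[str, int]:
    """Cut a size-selected insert uniformly from a genome.

    The insert length is uniform over ``size_range`` (inclusive) and the
    offset uniform over valid start positions.  Returns (subsequence, offset).
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1 or hi < lo:
        raise InvalidParameterError(f"bad size range {size_range}")
    if len(genome) < hi:
        raise InvalidParameterError(
            f"genome of {len(genome)} bp cannot yield inserts up to {hi} bp"
        )
    rng = _as_rng(seed)
    size = int(rng.integers(lo, hi + 1))
    offset = int(rng.integers(0, len(genome) - size + 1))
    return genome[offset : offset + size], offset


# ---------------------------------------------------------------------------
# Clone libraries
# ---------------------------------------------------------------------------


@dataclass
class LibraryParams:
    """Shape of a synthetic fosmid library."""

    n_clones: int
    taxon_mix: Mapping[str, float]
    insert_size_range: tuple[int, int] = (36_000, 48_000)
    active_gene_rate: float = 0.05
    linkage_config: Mapping[str, Sequence[Sequence[str]]] = field(default_factory=dict)
    genome_length: int = 500_000
    max_genes_per_clone: int = 3
    library_id: str = "LIB"

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise InvalidParameterError("n_clones must be >= 1")
        if not self.taxon_mix:
            raise InvalidParameterError("taxon_mix must not be empty")
        total = float(sum(self.taxon_mix.values()))
        if total <= 0:
            raise InvalidParameterError("taxon fractions must sum to a positive value")
        if abs(total - 1.0) > 1e-6:
            self.taxon_mix = {t: f / total for t, f in self.taxon_mix.items()}
        lo, hi = self.insert_size_range
        if not (1 <= lo <= hi <= self.genome_length):
            raise InvalidParameterError(
                "insert_size_range must lie within [1, genome_length]"
            )
        if self.active_gene_rate < 0:
            raise InvalidParameterError("active_gene_rate must be >= 0")


@dataclass
class Clone:
    clone_id: str
    library_id: str
    insert_seq: str
    true_taxon: str
    true_activities: frozenset[str]
    planted_families: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class CloneLibrary:
    """A synthetic clone collection with full ground truth."""

    library_id: str
    clones: list[Clone]
    params: LibraryParams
    taxon_models: dict[str, TaxonModel]
    family_map: dict[str, frozenset[str]]
    genomes: dict[str, str] = field(default_factory=dict, repr=False)

    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def by_id(self) -> dict[str, Clone]:
        return {c.clone_id: c for c in self.clones}

    def source_plate_layout(self) -> pd.DataFrame:
        """95 clones per source plate in row-major well order; H12 is the
        clone-free negative control on every plate."""
        rows = []
        for i, clone in enumerate(self.clones):
            plate = f"SP{i // len(CLONE_WELLS):04d}"
            well = CLONE_WELLS[i % len(CLONE_WELLS)]
            rows.append({"plate_id": plate, "well": well, "clone_id": clone.clone_id})
        n_plates = (len(self.clones) + len(CLONE_WELLS) - 1) // len(CLONE_WELLS)
        for p in range(n_plates):
            rows.append(
                {"plate_id": f"SP{p:04d}", "well": CONTROL_WELL, "clone_id": None}
            )
        frame = pd.DataFrame(rows, columns=["plate_id", "well", "clone_id"])
        return frame.sort_values(["plate_id", "well"], ignore_index=True)

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "clone_id": c.clone_id,
                "true_taxon": c.true_taxon,
                "insert_length": len(c.insert_seq),
                "planted_families": ";".join(f for f, _ in c.planted_families),
                "true_activities": ";".join(sorted(c.true_activities)),
            }
            for c in self.clones
        ]
        return pd.DataFrame(rows)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(c.insert_seq), id=c.clone_id, description="")
            for c in self.clones
        ]
        SeqIO.write(records, str(path), "fasta")


def build_library(
    params: LibraryParams,
    taxon_models: Sequence[TaxonModel],
    family_map: Mapping[str, frozenset[str]] | None = None,
    seed: int = 0,
) -> CloneLibrary:
    """Generate genomes and sample a clone library with planted activities.

    Per clone: the taxon is drawn from ``taxon_mix``; the insert is a
    uniform size-selected cut of that taxon's genome; a Poisson
    (``active_gene_rate``) number of gene-planting events (capped at
    ``max_genes_per_clone``) inserts enzyme families — either a linked
    family group from ``linkage_config`` or a single random family — and
    ``true_activities`` is the union of the substrates those families map to.
    """
    if family_map is None:
        from .panel import load_family_substrate_map

        family_map = load_family_substrate_map()
    else:
        family_map = dict(family_map)
    models = {m.taxon_id: m for m in taxon_models}
    missing = set(params.taxon_mix) - set(models)
    if missing:
        raise InvalidParameterError(f"taxon_mix references unmodelled taxa: {sorted(missing)}")
    for taxon, groups in params.linkage_config.items():
        for group in groups:
            unknown = set(group) - set(family_map)
            if unknown:
                raise InvalidParameterError(
                    f"linkage_config for {taxon} names unmapped families {sorted(unknown)}"
                )

    rng = _as_rng(seed)
    genomes = {
        t: generate_genome(models[t], params.genome_length, rng)
        for t in sorted(params.taxon_mix)
    }
    taxa = sorted(params.taxon_mix)
    fracs = np.array([params.taxon_mix[t] for t in taxa], dtype=float)
    plantable = sorted(f for f, subs in family_map.items() if subs)

    clones: list[Clone] = []
    width = max(5, len(str(params.n_clones)))
    for i in range(params.n_clones):
        taxon = taxa[rng.choice(len(taxa), p=fracs)]
        insert, _ = sample_insert(genomes[taxon], params.insert_size_range, rng)
        n_events = min(int(rng.poisson(params.active_gene_rate)), params.max_genes_per_clone)
        planted: list[tuple[str, int]] = []
        groups = params.linkage_config.get(taxon, [])
        for _ in range(n_events):
            if groups and rng.random() < 0.5:
                group = groups[int(rng.integers(len(groups)))]
                fams = list(group)
            elif plantable:
                fams = [plantable[int(rng.integers(len(plantable)))]]
            else:
                fams = []
            for fam in fams:
                planted.append((fam, int(rng.integers(len(insert)))))
        activities = frozenset().union(
            *(family_map.get(f, frozenset()) for f, _ in planted)
        ) if planted else frozenset()
        clones.append(
            Clone(
                clone_id=f"{params.library_id}_c{i:0{width}d}",
                library_id=params.library_id,
                insert_seq=insert,
                true_taxon=taxon,
                true_activities=activities,
                planted_families=sorted(planted, key=lambda t: t[1]),
            )
        )
    return CloneLibrary(
        library_id=params.library_id,
        clones=clones,
        params=params,
        taxon_models=models,
        family_map=dict(family_map),
        genomes=genomes,
    )


# ---------------------------------------------------------------------------
# Plate readings
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Additive plate-signal model.

    Scalar parameters apply to every substrate; a dict keyed by substrate
    overrides per substrate.  ``host_background`` models endogenous activity
    of the expression host (0 for the knockout host).  All values are in
    arbitrary plate-reader units; readings are clipped at 0.
    """

    background_mean: float | Mapping[str, float] = 5.0
    background_sd: float | Mapping[str, float] = 1.0
    host_background: float | Mapping[str, float] = 0.0
    active_signal_mean: float | Mapping[str, float] = 10.0
    active_signal_sd: float | Mapping[str, float] = 1.0
    seed: int = 0

    def _get(self, param, substrate: str) -> float:
        if isinstance(param, Mapping):
            return float(param.get(substrate, param.get("default", 0.0)))
        return float(param)

    def validate(self, substrates) -> None:
        for s in substrates:
            if self._get(self.background_sd, s) < 0 or self._get(self.active_signal_sd, s) < 0:
                raise InvalidParameterError("standard deviations must be >= 0")


def _simulate_plate_readings(
    well_actives: Mapping[tuple[str, str], int],
    plates: Sequence[str],
    panel: pd.DataFrame,
    noise: NoiseModel,
    timepoints: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Shared reading generator.

    ``well_actives`` maps (plate_id, well) -> number of active clones for the
    *current substrate*; it is re-queried per substrate via a callable
    convention: the mapping's values are dicts substrate -> count.
    """
    records = []
    for substrate, modality in zip(panel["substrate"], panel["modality"]):
        bg = noise._get(noise.background_mean, substrate)
        bg_sd = noise._get(noise.background_sd, substrate)
        host = noise._get(noise.host_background, substrate)
        act_mu = noise._get(noise.active_signal_mean, substrate)
        act_sd = noise._get(noise.active_signal_sd, substrate)
        for plate in plates:
            for well in WELLS:
                n_active = well_actives.get((plate, well), {}).get(substrate, 0)
                for tp in timepoints:
                    if modality == MODALITY_VISUAL:
                        value = 1.0 if n_active > 0 else 0.0
                    else:
                        value = bg + host + rng.normal(0.0, bg_sd)
                        if n_active:
                            value += act_mu * n_active + rng.normal(0.0, act_sd)
                        value = max(value, 0.0)
                    records.append((plate, well, substrate, tp, modality, value))
    return pd.DataFrame(
        records,
        columns=["plate_id", "well", "substrate", "timepoint", "modality", "value"],
    )


def simulate_readings(
    library: CloneLibrary,
    design: PoolingDesign,
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS_DEFAULT,
    panel: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate pooled assay-plate readings for a library under a design.

    Each pooled well reads background + host background + one additive
    contribution per pooled clone active on the substrate + Gaussian noise,
    clipped at 0, independently per timepoint.  Deterministic given
    ``noise.seed``.
    """
    panel = panel if panel is not None else load_substrate_panel()
    noise.validate(panel["substrate"])
    by_id = library.by_id()
    unknown = set(design.assignments["clone_id"]) - set(by_id)
    if unknown:
        raise ConsistencyError(
            f"design references clones absent from library: {sorted(unknown)[:3]}..."
        )
    well_actives: dict[tuple[str, str], dict[str, int]] = {}
    for row in design.assignments.itertuples(index=False):
        clone = by_id[row.clone_id]
        slot = well_actives.setdefault((row.assay_plate, row.assay_well), {})
        for substrate in clone.true_activities:
            slot[substrate] = slot.get(substrate, 0) + 1
    plates = sorted(design.assignments["assay_plate"].unique())
    rng = np.random.default_rng(noise.seed)
    return _simulate_plate_readings(well_actives, plates, panel, noise, timepoints, rng)


def simulate_individual_readings(
    library: CloneLibrary,
    clone_ids: Sequence[str],
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS_DEFAULT,
    panel: pd.DataFrame | None = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate expansion plates with one candidate clone per well.

    Candidates fill fresh plates 95 per plate (H12 control left empty);
    unused wells read pure background.  Returns (readings, layout) where
    layout maps (plate_id, well) -> clone_id.
    """
    panel = panel if panel is not None else load_substrate_panel()
    noise.validate(panel["substrate"])
    by_id = library.by_id()
    unknown = set(clone_ids) - set(by_id)
    if unknown:
        raise ConsistencyError(f"unknown candidate clones: {sorted(unknown)[:3]}...")
    layout_rows = []
    well_actives: dict[tuple[str, str], dict[str, int]] = {}
    for i, clone_id in enumerate(clone_ids):
        plate = f"EP{i // len(CLONE_WELLS):04d}"
        well = CLONE_WELLS[i % len(CLONE_WELLS)]
        layout_rows.append({"plate_id": plate, "well": well, "clone_id": clone_id})
        acts = by_id[clone_id].true_activities
        if acts:
            well_actives[(plate, well)] = {s: 1 for s in acts}
    n_plates = max(1, (len(clone_ids) + len(CLONE_WELLS) - 1) // len(CLONE_WELLS))
    plates = [f"EP{p:04d}" for p in range(n_plates)]
    rng = np.random.default_rng(noise.seed + 1 if seed is None else seed)
    readings = _simulate_plate_readings(well_actives, plates, panel, noise, timepoints, rng)
    layout = pd.DataFrame(layout_rows, columns=["plate_id", "well", "clone_id"])
    return readings, layout


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def synthesize_annotations(
    library: CloneLibrary,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a per-ORF family annotation table for the library.

    Each planted family is reported with probability ``1 - fn_rate`` with an
    e-value log-uniform in [1e-30, 1e-2].  Spurious records are added per
    clone as Binomial(n_nominal_orfs, fp_rate) draws of random families with
    e-values log-uniform in [1e-3, 1], straddling the conventional 0.1
    cut-off.  ORF ids are unique within a clone.  Byte-identical output for a
    fixed seed.
    """
    if not (0 <= fn_rate <= 1 and 0 <= fp_rate <= 1):
        raise InvalidParameterError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    families = sorted(library.family_map)
    rows = []
    for clone in library.clones:
        orf = 0
        for fam, _pos in clone.planted_families:
            if rng.random() >= fn_rate:
                orf += 1
                evalue = 10.0 ** rng.uniform(-30, -2)
                rows.append((clone.clone_id, f"orf_{orf:04d}", fam, evalue))
            else:
                orf += 1  # keep ORF numbering stable regardless of dropout
        # nominal ORF count: roughly one gene per 1.2 kb of insert
        n_orfs = max(1, len(clone.insert_seq) // 1200)
        n_fp = rng.binomial(n_orfs, fp_rate)
        for _ in range(n_fp):
            orf += 1
            fam = families[int(rng.integers(len(families)))]
            evalue = 10.0 ** rng.uniform(-3, 0)
            rows.append((clone.clone_id, f"orf_{orf:04d}", fam, evalue))
    return pd.DataFrame(rows, columns=["clone_id", "orf_id", "family", "evalue"])
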