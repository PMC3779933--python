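"""Study-condition validation experiments.

These functions run the package's methods under fixed, documented
conditions — pure-noise plates, planted-activity screens, multi-taxon
binning recoveries — and return the headline metric together with the
problem size.  They are shared by the test suite and the reproduction
script so both measure exactly the same procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import binning as tb
from . import screening as sc
from . import synthetic as syn
from .panel import load_substrate_panel

#: substrate used for the single-substrate screening experiments
_SUBSTRATE = "4-MUB-b-D-Xyloside"


def gaussian_false_positive_rate(
    seed: int, n_plates: int = 50, mean: float = 5.0, sd: float = 1.0
) -> tuple[float, int]:
    """Per-well positive rate of the mean + 2 SD rule on pure Gaussian noise.

    Simulates ``n_plates`` 96-well plates of N(mean, sd) readings (single
    timepoint) and applies the default hit-calling rule.  Returns
    (rate, n_wells).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plates):
        values = np.clip(rng.normal(mean, sd, 96), 0, None)
        for w, v in zip(sc.WELLS, values):
            rows.append((f"P{p:03d}", w, _SUBSTRATE, "24h", "fluorescence", v))
    readings = pd.DataFrame(rows, columns=sc.READING_COLUMNS)
    hits = sc.call_hits(readings)
    return float(hits.wells["positive"].mean()), len(hits.wells)


def confirmation_sensitivity(
    seed: int,
    n_assay_plates: int = 50,
    effect_sd: float = 6.0,
    active_rate: float = 0.003,
) -> tuple[float, int, int]:
    """Sensitivity of the full pool -> deconvolve -> confirm -> re-screen path.

    ``n_assay_plates`` pooled 96-well plates (1,520 clones each) carry
    planted single-substrate activities at ``active_rate`` per clone with an
    ``effect_sd``-sigma additive signal.  Returns
    (sensitivity, n_planted, n_false_confirmations).
    """
    n_clones = n_assay_plates * 1520
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=5)
    fam = {"GHX": frozenset({_SUBSTRATE})}
    panel = load_substrate_panel()
    panel1 = panel[panel["substrate"] == _SUBSTRATE].reset_index(drop=True)
    models = syn.random_taxon_models(1, int(seeds[0]))
    params = syn.LibraryParams(
        n_clones=n_clones,
        taxon_mix={"taxon_00": 1.0},
        insert_size_range=(1000, 1000),
        genome_length=20_000,
        active_gene_rate=active_rate,
        library_id="V",
    )
    lib = syn.build_library(params, models, fam, int(seeds[1]))
    design = sc.build_pooling_design(n_clones, clone_ids=lib.clone_ids())
    noise = syn.NoiseModel(
        active_signal_mean=effect_sd, active_signal_sd=0.5, seed=int(seeds[2])
    )
    readings = syn.simulate_readings(lib, design, noise, panel=panel1)
    hits = sc.call_hits(readings)
    cands = sc.deconvolve(hits, design)
    individual, layout = syn.simulate_individual_readings(
        lib, cands["clone_id"].tolist(), noise, panel=panel1, seed=int(seeds[3])
    )
    rescreen, _ = syn.simulate_individual_readings(
        lib, cands["clone_id"].tolist(), noise, panel=panel1, seed=int(seeds[4])
    )
    tags = dict(zip(cands["clone_id"], cands["substrates"]))
    profile = sc.confirm_clones(
        individual, layout, rescreen_readings=rescreen, candidate_substrates=tags
    )
    planted = [
        (c.clone_id, s) for c in lib.clones for s in c.true_activities
    ]
    confirmed = {(c, s) for c, subs in profile.activities.items() for s in subs}
    n_tp = sum(1 for p in planted if p in confirmed)
    sensitivity = n_tp / len(planted) if planted else float("nan")
    return sensitivity, len(planted), len(confirmed) - n_tp


def binning_recovery(
    seed: int,
    n_taxa: int = 5,
    clones_per_taxon: int = 30,
    concentration: float = 1.0,
    genome_length: int = 500_000,
    insert_size_range: tuple[int, int] = (36_000, 48_000),
    epochs: int = 20,
) -> tuple[float, int, int]:
    """Clone-level adjusted Rand index of ESOM TNF binning vs true taxa.

    Simulates ``n_taxa`` order-3 Markov taxa (Dirichlet ``concentration``
    rows; lower = more compositionally distinct), draws ``clones_per_taxon``
    size-selected inserts each, runs the full binning chain at defaults and
    scores the clone assignment against the generating taxon.  Returns
    (ARI, n_clones, n_fragments).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=3)
    models = syn.random_taxon_models(
        n_taxa, int(seeds[0]), order=3, concentration=concentration
    )
    genome_rng = np.random.default_rng(int(seeds[1]))
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    for m in models:
        genome = syn.generate_genome(m, genome_length, genome_rng)
        for j in range(clones_per_taxon):
            insert, _ = syn.sample_insert(genome, insert_size_range, genome_rng)
            clone_id = f"{m.taxon_id}_c{j:03d}"
            sequences[clone_id] = insert
            truth[clone_id] = m.taxon_id
    result = tb.bin_clones(
        sequences, esom=tb.EsomParams(seed=int(seeds[2]), epochs=epochs)
    )
    assigned = result.assignments
    ari = float(
        adjusted_rand_score(
            [truth[c] for c in assigned["clone_id"]], assigned["bin"]
        )
    )
    return ari, len(assigned), len(result.tnf)
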