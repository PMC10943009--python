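"""End-to-end benchmark workflows on synthetic data with planted truth.

Each function builds its own inputs with the synthetic-data generator,
runs the relevant slice of the pipeline, and measures recovery against the
planted ground truth.  They serve three purposes: executable documentation
of how the pieces compose, the substance behind the acceptance checks, and
quick sanity benchmarks after refactoring.

Where a workflow validates a formula (signal, gain, specificity, overlap),
the reference value is recomputed by deliberately naive brute force —
plain Python loops over cells and pixels — independent of the vectorized
implementations under test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import design, quantify, reference, score, simulate, spatial

__all__ = [
    "formula_oracle_errors",
    "manders_oracle_error",
    "planted_module_recovery",
    "end_to_end_imaging",
    "proximity_depletion",
]


# ---------------------------------------------------------------------------
# formula oracles


def _brute_gene_signal(cell_scaled, gene_row, mask, k):
    vals = [cell_scaled[gene_row][i] for i in range(len(mask)) if mask[i]]
    return k * sum(vals) / len(vals)


def formula_oracle_errors(seed: int = 0, n_fixtures: int = 20) -> dict[str, float]:
    """Max |vectorized - brute force| for the signal model on random fixtures.

    Covers gene signal, panel signal, both Signal Gain modes, both Signal
    Specificity Ratio modes and the module-cell matrix.
    """
    rng = np.random.default_rng(seed)
    worst = {"signal": 0.0, "sg": 0.0, "ssr": 0.0, "module_cell": 0.0}
    for _ in range(n_fixtures):
        n_genes = int(rng.integers(6, 15))
        n_cells = int(rng.integers(10, 40))
        n_clusters = int(rng.integers(2, 5))
        cell_scaled = rng.uniform(0.1, 50.0, (n_genes, n_cells))
        labels = rng.integers(0, n_clusters, n_cells)
        # guarantee every cluster is populated
        labels[:n_clusters] = np.arange(n_clusters)
        labels = np.array([f"t{i}" for i in labels], dtype=object)
        gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
        views = reference.NormalizedViews(
            cell_scaled=cell_scaled,
            log_view=np.log1p(cell_scaled),
            gene_scaled=reference.standardize_genes(np.log1p(cell_scaled)),
            gene_ids=gene_ids,
            cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
            cell_labels=labels,
        )
        size = int(rng.integers(2, n_genes))
        genes = [f"g{i}" for i in rng.choice(n_genes, size, replace=False)]
        probes = {g: int(rng.integers(1, 30)) for g in genes}
        mod = design.PanelModule("M", genes, probes_per_gene=probes,
                                 reference_genes=[genes[0]])
        target = "t0"
        mask = labels == target

        brute_signals = {
            g: _brute_gene_signal(cell_scaled, int(g[1:]), mask, probes[g])
            for g in genes
        }
        brute_panel = sum(brute_signals.values())
        worst["signal"] = max(
            worst["signal"],
            abs(score.panel_signal(views, mod, target) - brute_panel),
            max(
                abs(score.gene_signal(views, g, target, k=probes[g]) - bs)
                for g, bs in brute_signals.items()
            ),
        )
        worst["sg"] = max(
            worst["sg"],
            abs(score.signal_gain(views, mod, target, "general")
                - brute_panel / brute_signals[genes[0]]),
            abs(score.signal_gain(views, mod, target, "conservative")
                - brute_panel / max(brute_signals.values())),
        )
        off = {}
        for cl in np.unique(labels):
            if cl == target:
                continue
            m2 = labels == cl
            off[cl] = sum(
                _brute_gene_signal(cell_scaled, int(g[1:]), m2, probes[g])
                for g in genes
            )
        ssr_c, _ = score.signal_specificity_ratio(views, mod, target, "conservative")
        ssr_g, _ = score.signal_specificity_ratio(views, mod, target, "general")
        worst["ssr"] = max(
            worst["ssr"],
            abs(ssr_c - brute_panel / max(off.values())),
            abs(ssr_g - brute_panel / sum(off.values())),
        )
        mcm = score.module_cell_matrix(views, design.GenePanel([mod]))
        for c in range(n_cells):
            brute = sum(cell_scaled[int(g[1:]), c] for g in genes)
            worst["module_cell"] = max(
                worst["module_cell"], abs(mcm.iloc[0, c] - brute)
            )
    return worst


def manders_oracle_error(seed: int = 0, n_fixtures: int = 50,
                         shape: tuple[int, int] = (8, 8)) -> float:
    """Max |M1/M2 - pixel-count enumeration| over random image pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        a = rng.random(shape)
        b = rng.random(shape)
        t1, t2 = rng.uniform(0.2, 0.8, 2)
        res = spatial.manders_overlap(a, b, t1=t1, t2=t2)
        n1 = n2 = both = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                s1, s2 = a[i, j] > t1, b[i, j] > t2
                n1 += s1
                n2 += s2
                both += s1 and s2
        worst = max(
            worst,
            abs(res.M1 - (both / n1 if n1 else 0.0)),
            abs(res.M2 - (both / n2 if n2 else 0.0)),
        )
    return worst


# ---------------------------------------------------------------------------
# planted-module recovery (panel design at fold 8)


@dataclass
class ModuleRecoveryResult:
    aris: list[float]
    min_signal_gain: float
    min_ssr: float
    n_cells: int
    n_genes: int


def _planted_config(seed, n_cells, n_genes, n_modules, genes_per_module,
                    fold_change):
    mods = [
        simulate.ModuleSpec(
            f"m{t}",
            tuple(range(genes_per_module * t, genes_per_module * (t + 1))),
            t,
            fold_change,
        )
        for t in range(n_modules)
    ]
    return simulate.SimulationConfig(
        n_cells=n_cells, n_genes=n_genes, n_cell_types=n_modules,
        modules=mods, seed=seed,
    )


def planted_module_recovery(
    seed: int = 0,
    n_seeds: int = 10,
    n_cells: int = 3000,
    n_genes: int = 5000,
    n_modules: int = 5,
    genes_per_module: int = 8,
    fold_change: float = 8.0,
    min_corr: float = 0.7,
    min_partners: int = 5,
    edge_threshold: float = 0.6,
) -> ModuleRecoveryResult:
    """Feature-gene candidate selection + Leiden vs planted membership.

    For each replicate: simulate a reference, select candidate genes with
    at least ``min_partners`` partners at r > ``min_corr`` on the log view,
    partition the thresholded correlation graph, and score the recovered
    partition by ARI against the planted module membership.  Each recovered
    module becomes a panel module targeted at its majority planted type and
    is scored for conservative Signal Gain and SSR.
    """
    aris: list[float] = []
    sgs: list[float] = []
    ssrs: list[float] = []
    for rep in range(n_seeds):
        cfg = _planted_config(
            seed * 1009 + rep, n_cells, n_genes, n_modules, genes_per_module,
            fold_change,
        )
        ref, truth = simulate.simulate_reference(cfg)
        views = reference.normalize_views(ref)
        corr = design.pearson_matrix(views.log_view)
        cand = design.feature_gene_candidates(corr, min_corr, min_partners)
        cand_ids = views.gene_ids[cand]
        graph = design.correlation_graph(
            corr[np.ix_(cand, cand)], cand_ids, edge_threshold
        )
        labels = design.leiden_modules(graph, seed=seed)
        planted = truth.module_membership
        overlap = [i for i, g in enumerate(cand_ids) if g in planted]
        aris.append(
            score.adjusted_rand_index(
                labels[overlap], [planted[cand_ids[i]] for i in overlap]
            )
        )
        for c in np.unique(labels):
            genes = [str(g) for g in cand_ids[labels == c]]
            if len(genes) < 2:
                continue
            majority = Counter(
                planted.get(g) for g in genes
            ).most_common(1)[0][0]
            if majority is None:
                continue
            target = f"type{truth.module_target_types[majority]}"
            mod = design.PanelModule(str(c), genes, target_label=target)
            sgs.append(score.signal_gain(views, mod, target, "conservative"))
            ssrs.append(
                score.signal_specificity_ratio(views, mod, target, "conservative")[0]
            )
    return ModuleRecoveryResult(
        aris=[float(a) for a in aris],
        min_signal_gain=float(min(sgs)),
        min_ssr=float(min(ssrs)),
        n_cells=n_cells,
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# end-to-end imaging round trip


@dataclass
class EndToEndResult:
    ari: float
    registration_max_error_px: float
    outlier_discarded: bool
    n_cells_passing: int
    n_clusters: int


def end_to_end_imaging(
    seed: int = 0,
    n_cells: int = 400,
    n_genes: int = 60,
    n_modules: int = 5,
    fold_change: float = 16.0,
    noise_fraction: float = 0.05,
    image_shape: tuple[int, int] = (400, 400),
) -> EndToEndResult:
    """Simulate, image, register, quantify (dilation 15 / 15th-pct QC), cluster.

    Planted per-round shifts include one 60-px outlier used only to check
    the shift-acceptance policy; the pipeline applies per-round measured
    shifts.  Camera noise is ``noise_fraction`` of the median planted
    signal.  Returns clustering ARI against planted cell types over
    QC-passing cells and the worst registration error on the sub-50-px
    rounds.
    """
    cfg = _planted_config(seed, n_cells, n_genes, n_modules, 8, fold_change)
    ref, truth = simulate.simulate_reference(cfg)
    sig = truth.per_cell_module_signal
    noise_sd = noise_fraction * float(np.median(sig[sig > 0]))
    planted_shifts = {
        "m0": (0.0, 0.0),
        "m1": (3.0, -2.0),
        "m2": (-4.0, 5.0),
        "m3": (1.5, 2.5),
        "m4": (60.0, 0.0),  # beyond the 50-px acceptance bound
    }
    stack, nuclei = simulate.simulate_tissue_images(
        truth, image_shape, shifts=planted_shifts, noise_sd=noise_sd,
        background_level=5.0, include_background_round=True, seed=seed + 7,
    )
    measured = {
        m: quantify.register_image(stack.rounds[m], stack.rounds["nuclear"])
        for m in stack.module_rounds
    }
    reg_err = max(
        max(abs(measured[m][0] - planted_shifts[m][0]),
            abs(measured[m][1] - planted_shifts[m][1]))
        for m in stack.module_rounds
        if max(map(abs, planted_shifts[m])) <= 50
    )
    averaged = quantify.shift_policy(measured, max_abs_px=50, mode="fov_average")
    outlier_gone = not np.allclose(averaged["m0"], measured["m4"]) and (
        abs(averaged["m0"][0]) < 50
    )

    applied = quantify.shift_policy(measured, max_abs_px=50, mode="per_image")
    cells = quantify.dilate_masks(nuclei, 15)
    matrix = quantify.intensity_matrix(stack, cells, shifts=applied)
    matrix = quantify.qc_cells(matrix, "total_percentile", percentile=15)
    res = spatial.cluster_cells(
        matrix, resolution=0.8, n_pcs=n_modules, n_neighbors=20, seed=seed,
        algorithm="leiden", normalize_total=True, log_transform=True,
    )
    passing = ~matrix.cells["qc_flag"].to_numpy()
    ari = score.adjusted_rand_index(
        res.labels, truth.cell_type_labels[passing]
    )
    return EndToEndResult(
        ari=float(ari),
        registration_max_error_px=float(reg_err),
        outlier_discarded=bool(outlier_gone),
        n_cells_passing=int(passing.sum()),
        n_clusters=int(len(np.unique(res.labels))),
    )


# ---------------------------------------------------------------------------
# proximity depletion analogue


def proximity_depletion(
    seed: int = 0,
    n_per_group: int = 500,
    keep_probability: float = 0.5,
    radius_um: float = 100.0,
    n_query: int = 6000,
) -> spatial.ProximityResult:
    """Neighborhood counts with query cells depleted around group B.

    Groups A and B occupy disjoint 1000x1000 um regions; query cells are
    uniform over both, then thinned to ``keep_probability`` within
    ``radius_um`` of any B cell — a planted two-fold depletion when the
    keep probability is 0.5.
    """
    rng = np.random.default_rng(seed)
    a = np.c_[rng.uniform(0, 1000, n_per_group), rng.uniform(0, 1000, n_per_group)]
    b = np.c_[rng.uniform(0, 1000, n_per_group),
              rng.uniform(2000, 3000, n_per_group)]
    query = np.c_[rng.uniform(0, 1000, n_query), rng.uniform(0, 3000, n_query)]
    from scipy.spatial import cKDTree

    near_b = cKDTree(b).query_ball_point(query, radius_um, return_length=True) > 0
    drop = near_b & (rng.random(n_query) > keep_probability)
    return spatial.proximity_counts(
        a, b, query[~drop], radius_um=radius_um, pixel_size=1.0
    )
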