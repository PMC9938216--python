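"""Synthetic-data generators with planted ground truth.

Each generator emulates one input of the analysis chain with the statistical
structure the downstream stage assumes, and returns the planted truth
alongside the data so recovery can be tested:

* :func:`gen_quant_table` — ¹⁴N/¹⁵N protein ratio tables (log-normal, planted
  genotype effects, gross outliers, missing cells);
* :func:`gen_gene_universe` — a gene universe with named sets and a query
  list whose overlap with each set is planted at a configurable fold over
  chance (noncentral-hypergeometric sampling);
* :func:`gen_ppi_graph` — a scale-free-ish interaction graph with a planted
  high-degree hub;
* :func:`gen_traces` — ROI × frame fluorescence traces built from a drifting
  baseline, Gaussian noise, independent per-ROI transients and synchronized
  network events with per-ROI onset jitter;
* :func:`gen_seizure_cohort` — kainate-assay cohorts with genotype-dependent
  GTCS incidence, Weibull onset latencies censored at the 2-h observation
  end, Racine scores and survival;
* :func:`gen_spectral_counts` — bait-vs-IgG spectral count tables for
  interactome calling.

Every generator is a pure function of its :class:`SynthConfig`: identical
config (including ``seed``) gives byte-identical output.  Independent RNG
sub-streams are derived from ``(seed, stream, index)`` tuples so that e.g.
adding ROIs does not reshuffle the draws of earlier ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EventRaster, GeneSetCollection, TraceMatrix

__all__ = [
    "SynthConfig",
    "ConfigError",
    "gen_quant_table",
    "gen_gene_universe",
    "gen_ppi_graph",
    "gen_traces",
    "gen_seizure_cohort",
    "gen_spectral_counts",
]

_LN2 = math.log(2.0)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


@dataclass
class SynthConfig:
    """Parameters of all synthetic generators.

    Defaults mirror the study conditions the pipeline was designed around:
    5 biological replicates per genotype, Cal520 culture recordings at
    2 frames/s for 10 min, kainate cohorts of 16 wild-type and 17
    duplication animals with ~44% vs ~82% GTCS incidence, and a 208-protein
    scale bait interactome.  See ``docs/methods.md`` for the rationale of
    values the underlying experiments do not pin down.
    """

    seed: int = 0

    # -- quantification table -------------------------------------------------
    n_proteins: int = 1000
    n_replicates_per_genotype: int = 5
    effect_log2fc: float = 1.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    noise_sd: float = 0.2
    outlier_rate: float = 0.01
    missing_rate: float = 0.05

    # -- gene universe --------------------------------------------------------
    n_genes_universe: int = 4000
    set_sizes: list[int] = field(default_factory=lambda: [100, 100, 100])
    planted_enrichment_fold: float = 3.0
    n_planted_sets: int = 1  # leading sets get the fold; the rest are null
    query_size: int = 200

    # -- interaction graph ----------------------------------------------------
    graph_n: int = 100
    graph_m: int = 2
    hub_extra_degree: int = 12

    # -- fluorescence traces --------------------------------------------------
    n_rois: int = 150
    duration_s: float = 600.0
    fs: float = 2.0
    transient_amplitude: float = 0.5
    transient_halfwidth_s: float = 1.0
    trace_noise_sd: float = 0.03
    event_rate_hz: float = 0.02
    network_event_rate_hz: float = 0.02
    coactive_fraction: float = 0.6
    jitter_s: float = 0.2
    baseline_level: float = 1.0
    drift_amplitude: float = 0.02
    drift_period_s: float = 300.0

    # -- seizure cohort -------------------------------------------------------
    cohort_sizes: dict[str, int] = field(default_factory=lambda: {"WT": 16, "DUP": 17})
    gtcs_prob: dict[str, float] = field(default_factory=lambda: {"WT": 0.44, "DUP": 0.82})
    latency_scale_s: dict[str, float] = field(
        default_factory=lambda: {"WT": 3600.0, "DUP": 1800.0}
    )
    observation_end_s: float = 7200.0
    death_prob_given_gtcs: float = 0.5

    # -- spectral counts ------------------------------------------------------
    n_true_interactors: int = 50
    n_background_proteins: int = 500
    bait_mean: float = 10.0
    igg_mean: float = 2.0
    igg_zero_fraction: float = 0.2
    n_count_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = [
            "n_proteins",
            "n_replicates_per_genotype",
            "n_genes_universe",
            "graph_n",
            "n_rois",
            "query_size",
            "n_count_replicates",
        ]
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "frac_up",
            "frac_down",
            "outlier_rate",
            "missing_rate",
            "coactive_fraction",
            "igg_zero_fraction",
            "death_prob_given_gtcs",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down must not exceed 1")
        if not self.fs > 0:
            raise ConfigError("fs must be positive")
        for name in ("noise_sd", "trace_noise_sd", "jitter_s", "hub_extra_degree", "graph_m",
                     "event_rate_hz", "network_event_rate_hz", "transient_halfwidth_s",
                     "transient_amplitude", "duration_s", "observation_end_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.planted_enrichment_fold < 0:
            raise ConfigError("planted_enrichment_fold must be >= 0")
        if self.n_planted_sets < 0:
            raise ConfigError("n_planted_sets must be >= 0")
        if any(s < 1 for s in self.set_sizes):
            raise ConfigError("set_sizes entries must be >= 1")
        if sum(self.set_sizes) > self.n_genes_universe:
            raise ConfigError("set_sizes exceed n_genes_universe")
        if self.query_size > self.n_genes_universe:
            raise ConfigError("query_size exceeds n_genes_universe")
        for g, p in self.gtcs_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"gtcs_prob[{g}] must be in [0, 1]")
        for g, n in self.cohort_sizes.items():
            if n < 1:
                raise ConfigError(f"cohort_sizes[{g}] must be >= 1")
        for g, s in self.latency_scale_s.items():
            if s <= 0:
                raise ConfigError(f"latency_scale_s[{g}] must be positive")
        if self.bait_mean < 0 or self.igg_mean < 0:
            raise ConfigError("bait_mean and igg_mean must be nonnegative")
        if self.n_true_interactors < 0 or self.n_background_proteins < 0:
            raise ConfigError("interactor counts must be >= 0")

    def replace(self, **kwargs) -> "SynthConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SynthConfig(**current)


def _rng(cfg: SynthConfig, *stream: int) -> np.random.Generator:
    """Independent substream keyed by (seed, *stream)."""
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# (a) quantification table
# ---------------------------------------------------------------------------

def gen_quant_table(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a protein × replicate ¹⁴N/¹⁵N ratio table.

    Log2 ratios are drawn ``N(0, noise_sd)``; proteins planted as "up"
    ("down") are shifted by ``+effect_log2fc`` (``-effect_log2fc``) in the
    duplication replicates only, so the wild-type arm stays at baseline.
    A fraction ``outlier_rate`` of cells is replaced by gross outliers
    (3–6 extra log2 units, random sign) and a fraction ``missing_rate`` of
    cells is dropped.  Peptide-fit quality ``r2`` ~ Beta(8, 2).

    Returns
    -------
    table : DataFrame
        Columns ``protein_id, replicate_id, genotype, ratio, r2``.
    truth : DataFrame
        Columns ``protein_id, label`` with label in {up, down, null}.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_proteins
    n_up = int(round(cfg.frac_up * n)) if cfg.effect_log2fc != 0 else 0
    n_down = int(round(cfg.frac_down * n)) if cfg.effect_log2fc != 0 else 0
    proteins = np.array([f"P{i:05d}" for i in range(n)])
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    labels[perm[:n_up]] = "up"
    labels[perm[n_up : n_up + n_down]] = "down"
    effect = np.where(labels == "up", cfg.effect_log2fc,
                      np.where(labels == "down", -cfg.effect_log2fc, 0.0))

    reps = [(f"WT_{i + 1}", "WT") for i in range(cfg.n_replicates_per_genotype)] + [
        (f"DUP_{i + 1}", "DUP") for i in range(cfg.n_replicates_per_genotype)
    ]
    rows = []
    for rep_id, genotype in reps:
        log2r = rng.normal(0.0, cfg.noise_sd, size=n)
        if genotype == "DUP":
            log2r = log2r + effect
        out = rng.random(n) < cfg.outlier_rate
        if out.any():
            shift = rng.uniform(3.0, 6.0, size=int(out.sum()))
            sign = rng.choice([-1.0, 1.0], size=int(out.sum()))
            log2r[out] += shift * sign
        keep = rng.random(n) >= cfg.missing_rate
        r2 = rng.beta(8.0, 2.0, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": proteins[keep],
                    "replicate_id": rep_id,
                    "genotype": genotype,
                    "ratio": np.exp2(log2r[keep]),
                    "r2": r2[keep],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"protein_id": proteins, "label": labels})
    return table, truth


# ---------------------------------------------------------------------------
# (b) gene universe with planted set enrichment
# ---------------------------------------------------------------------------

def _solve_odds_for_mean(N: int, K: int, q: int, target_mean: float) -> float:
    """Odds parameter of Fisher's noncentral hypergeometric with given mean."""
    lo, hi = 1e-8, 1e8

    def mean_at(w: float) -> float:
        return float(stats.nchypergeom_fisher.mean(N, K, q, w))

    from scipy.optimize import brentq

    f = lambda w: mean_at(w) - target_mean
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigError("planted_enrichment_fold infeasible for set/query sizes")
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def gen_gene_universe(cfg: SynthConfig) -> tuple[GeneSetCollection, list[str]]:
    """Simulate a gene universe, disjoint named sets and a query list.

    The first ``n_planted_sets`` sets are planted: the overlap of the query
    (size q) with a planted set of size K in a universe of size N is drawn
    from Fisher's noncentral hypergeometric distribution with the odds
    parameter solved so that the expected overlap equals
    ``planted_enrichment_fold × qK/N`` (the chance expectation).  The
    remaining sets, and every set when ``fold = 1``, draw their overlap
    from the central hypergeometric null.

    Returns the collection (with the universe) and the query gene list.
    """
    N = cfg.n_genes_universe
    q = cfg.query_size
    fold = cfg.planted_enrichment_fold
    rng = _rng(cfg, 1)
    universe = [f"G{i:05d}" for i in range(N)]
    order = rng.permutation(N)

    sets: dict[str, set[str]] = {}
    pos = 0
    overlaps: list[np.ndarray] = []
    total_overlap = 0
    for si, K in enumerate(cfg.set_sizes):
        members = [universe[j] for j in order[pos : pos + K]]
        pos += K
        set_fold = fold if si < cfg.n_planted_sets else 1.0
        target = set_fold * q * K / N
        if target > min(K, q) + 1e-9:
            raise ConfigError(
                "planted_enrichment_fold requires overlap "
                f"{target:.1f} > min(set_size={K}, query_size={q})"
            )
        if abs(set_fold - 1.0) < 1e-12:
            k = int(stats.hypergeom.rvs(N, K, q, random_state=rng))
        elif set_fold == 0.0:
            k = 0
        else:
            odds = _solve_odds_for_mean(N, K, q, target)
            k = int(stats.nchypergeom_fisher.rvs(N, K, q, odds, random_state=rng))
        k = min(k, K, q - total_overlap)
        chosen = rng.choice(K, size=k, replace=False)
        overlaps.append(np.array([members[j] for j in chosen], dtype=object))
        total_overlap += k
        sets[f"set_{si:02d}"] = set(members)

    in_sets = set().union(*sets.values()) if sets else set()
    outside = [g for g in universe if g not in in_sets]
    n_rest = q - total_overlap
    rest = rng.choice(len(outside), size=n_rest, replace=False)
    query = [g for ov in overlaps for g in ov] + [outside[j] for j in rest]
    return GeneSetCollection(sets=sets, universe=set(universe)), query


# ---------------------------------------------------------------------------
# (c) interaction graph with planted hub
# ---------------------------------------------------------------------------

def gen_ppi_graph(cfg: SynthConfig):
    """Simulate an undirected interaction graph with a planted hub.

    The base graph is Barabási–Albert with attachment parameter ``graph_m``
    (``graph_m = 0`` gives an edgeless base, useful for constructing stars).
    The hub is planted on the highest-degree base node (so the label is the
    true degree maximum by construction) and receives ``hub_extra_degree``
    additional edges to uniformly chosen non-neighbors.  No self-loops or
    parallel edges; the hub's name is stored in ``G.graph["planted_hub"]``.
    """
    import networkx as nx

    if cfg.graph_n < 3:
        raise ConfigError("graph_n must be >= 3")
    rng = _rng(cfg, 2)
    n = cfg.graph_n
    if cfg.graph_m == 0:
        base = nx.empty_graph(n)
    else:
        base = nx.barabasi_albert_graph(n, min(cfg.graph_m, n - 1),
                                        seed=int(rng.integers(2**31)))
    names = {i: f"G{i:04d}" for i in range(n)}
    g = nx.relabel_nodes(base, names)
    # plant on the top base node so the hub label is the true degree maximum
    hub = min(g.nodes, key=lambda v: (-g.degree(v), v))
    non_neighbors = sorted(set(g.nodes) - set(g.neighbors(hub)) - {hub})
    k = min(cfg.hub_extra_degree, len(non_neighbors))
    if k > 0:
        chosen = rng.choice(len(non_neighbors), size=k, replace=False)
        g.add_edges_from((hub, non_neighbors[j]) for j in chosen)
    g.graph["planted_hub"] = hub
    return g


# ---------------------------------------------------------------------------
# (d) fluorescence traces
# ---------------------------------------------------------------------------

def _add_transient(trace: np.ndarray, onset_frame: int, amplitude: float,
                   tau_frames: float) -> None:
    """Add an instantaneous-rise exponential-decay bump in place."""
    n = trace.size
    if onset_frame >= n or onset_frame < 0:
        return
    t = np.arange(n - onset_frame)
    trace[onset_frame:] += amplitude * np.exp(-t / tau_frames)


def gen_traces(cfg: SynthConfig) -> tuple[TraceMatrix, EventRaster, np.ndarray]:
    """Simulate raw fluorescence traces with planted transients.

    Transients are instantaneous-rise exponential-decay bumps whose decay
    constant is set so the full width at half maximum equals
    ``transient_halfwidth_s``.  Network events occur at rate
    ``network_event_rate_hz``, each recruiting
    ``ceil(coactive_fraction · n_rois)`` distinct ROIs with per-ROI onset
    jitter ~ N(0, jitter_s); independent per-ROI transients occur at
    ``event_rate_hz``.  The raw trace of ROI r is

        F_r(t) = F0(t) · (1 + s_r(t)) + F0_level · ε_r(t),

    with F0(t) a slow sinusoidal drift around ``baseline_level`` and
    ε ~ N(0, trace_noise_sd), so ``s`` is expressed in ΔF/F₀ units.

    Returns
    -------
    traces : TraceMatrix (raw units)
    truth : EventRaster
        Ground-truth peak raster and per-event metadata.
    network_event_times_s : ndarray
        Nominal onset time of each planted network event.
    """
    n_frames = int(round(cfg.duration_s * cfg.fs))
    if n_frames < 10:
        raise ConfigError("duration_s * fs must be >= 10 frames")
    n = cfg.n_rois
    tau_frames = (cfg.transient_halfwidth_s / _LN2) * cfg.fs

    rng_net = _rng(cfg, 3, 0)
    n_events = rng_net.poisson(cfg.network_event_rate_hz * cfg.duration_s)
    # keep events away from the edges so full transients fit in the recording
    lo, hi = 0.05 * cfg.duration_s, 0.9 * cfg.duration_s
    event_times = np.sort(rng_net.uniform(lo, hi, size=n_events))
    n_recruit = math.ceil(cfg.coactive_fraction * n)
    recruits = [rng_net.choice(n, size=n_recruit, replace=False) for _ in event_times]

    traces = np.empty((n, n_frames))
    raster = np.zeros((n, n_frames), dtype=bool)
    meta = {"roi": [], "peak_frame": [], "amplitude": [], "halfwidth_s": [], "network_event": []}
    t_s = np.arange(n_frames) / cfg.fs
    phase_rng = _rng(cfg, 3, 1)
    phase = phase_rng.uniform(0, 2 * math.pi)
    f0 = cfg.baseline_level * (
        1.0 + cfg.drift_amplitude * np.sin(2 * math.pi * t_s / cfg.drift_period_s + phase)
    )

    for roi in range(n):
        r = _rng(cfg, 3, 2, roi)
        s = np.zeros(n_frames)
        onsets: list[tuple[int, int]] = []  # (frame, network event index or -1)
        for ei, (et, rec) in enumerate(zip(event_times, recruits)):
            if roi in rec:
                onset = et + r.normal(0.0, cfg.jitter_s)
                onsets.append((int(round(onset * cfg.fs)), ei))
        n_ind = r.poisson(cfg.event_rate_hz * cfg.duration_s)
        for u in r.uniform(0, cfg.duration_s, size=n_ind):
            onsets.append((int(round(u * cfg.fs)), -1))
        for frame, ei in onsets:
            if not 0 <= frame < n_frames:
                continue
            _add_transient(s, frame, cfg.transient_amplitude, tau_frames)
            if cfg.transient_amplitude > 0:
                raster[roi, frame] = True
                meta["roi"].append(roi)
                meta["peak_frame"].append(frame)
                meta["amplitude"].append(cfg.transient_amplitude)
                meta["halfwidth_s"].append(cfg.transient_halfwidth_s)
                meta["network_event"].append(ei)
        noise = (r.normal(0.0, cfg.trace_noise_sd, size=n_frames)
                 if cfg.trace_noise_sd > 0 else 0.0)
        traces[roi] = f0 * (1.0 + s) + cfg.baseline_level * noise

    tm = TraceMatrix(traces=traces, fs=cfg.fs, kind="calcium_culture", units="raw")
    truth = EventRaster(raster=raster, fs=cfg.fs,
                        events=pd.DataFrame(meta).sort_values(["roi", "peak_frame"],
                                                              ignore_index=True))
    return tm, truth, event_times


# ---------------------------------------------------------------------------
# (e) seizure cohort
# ---------------------------------------------------------------------------

def gen_seizure_cohort(cfg: SynthConfig) -> pd.DataFrame:
    """Simulate a kainate seizure cohort.

    Per animal: GTCS ~ Bernoulli(gtcs_prob[genotype]); for GTCS animals the
    onset latency follows a Weibull(shape 2) scaled by
    ``latency_scale_s[genotype]`` truncated to the observation window, and
    non-GTCS animals are censored at ``observation_end_s``.  The 1-h Racine
    score is drawn 6–7 for GTCS animals (7 = death, probability
    ``death_prob_given_gtcs``) and 1–5 otherwise; ``died`` is consistent
    with score 7 and death times follow the GTCS onset.

    Columns: ``animal_id, genotype, gtcs, gtcs_latency_s, racine_1h, died,
    death_time_s`` (latency/death times equal ``observation_end_s`` when
    censored, with the boolean indicating the event).
    """
    rows = []
    shape = 2.0
    for gi, (genotype, n_animals) in enumerate(sorted(cfg.cohort_sizes.items())):
        p = cfg.gtcs_prob.get(genotype)
        scale = cfg.latency_scale_s.get(genotype)
        if p is None or scale is None:
            raise ConfigError(f"gtcs_prob/latency_scale_s missing genotype {genotype!r}")
        r = _rng(cfg, 4, gi)
        for a in range(n_animals):
            gtcs = bool(r.random() < p)
            if gtcs:
                # inverse-CDF draw from Weibull truncated at the observation end
                cmax = 1.0 - math.exp(-((cfg.observation_end_s / scale) ** shape))
                u = r.uniform(0.0, cmax)
                latency = scale * (-math.log(1.0 - u)) ** (1.0 / shape)
                died = bool(r.random() < cfg.death_prob_given_gtcs)
                racine = 7 if died else 6
                death_time = (
                    min(latency + r.exponential(600.0), cfg.observation_end_s * 0.999)
                    if died
                    else cfg.observation_end_s
                )
            else:
                latency = cfg.observation_end_s
                died = False
                racine = int(r.integers(1, 6))
                death_time = cfg.observation_end_s
            rows.append(
                {
                    "animal_id": f"{genotype}_{a + 1:03d}",
                    "genotype": genotype,
                    "gtcs": gtcs,
                    "gtcs_latency_s": latency,
                    "racine_1h": racine,
                    "died": died,
                    "death_time_s": death_time,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# (f) spectral counts
# ---------------------------------------------------------------------------

def gen_spectral_counts(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate bait-vs-IgG spectral counts for interactome calling.

    True interactors draw bait counts Poisson(``bait_mean``) against IgG
    counts whose mean is at most ``bait_mean / 4`` (so the 2-fold criterion
    is attainable), with a fraction ``igg_zero_fraction`` of them absent
    from the control entirely.  Background proteins have equal means
    (``igg_mean``) in both arms.

    Returns
    -------
    counts : DataFrame indexed by protein with columns ``bait_1.., igg_1..``.
    truth : DataFrame with columns ``protein_id, label`` in
        {interactor, background}.
    """
    rng = _rng(cfg, 5)
    nrep = cfg.n_count_replicates
    rows, labels, ids = [], [], []
    true_igg_mean = min(cfg.igg_mean, cfg.bait_mean / 4.0)
    for i in range(cfg.n_true_interactors):
        igg_mu = 0.0 if rng.random() < cfg.igg_zero_fraction else true_igg_mean
        rows.append(
            np.concatenate(
                [rng.poisson(cfg.bait_mean, nrep), rng.poisson(igg_mu, nrep)]
            )
        )
        ids.append(f"INT{i:04d}")
        labels.append("interactor")
    for i in range(cfg.n_background_proteins):
        rows.append(
            np.concatenate(
                [rng.poisson(cfg.igg_mean, nrep), rng.poisson(cfg.igg_mean, nrep)]
            )
        )
        ids.append(f"BG{i:04d}")
        labels.append("background")
    cols = [f"bait_{j + 1}" for j in range(nrep)] + [f"igg_{j + 1}" for j in range(nrep)]
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"), columns=cols)
    truth = pd.DataFrame({"protein_id": ids, "label": labels})
    return counts, truth
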