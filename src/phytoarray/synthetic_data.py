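"""Seeded synthetic inputs and packaged fixtures.

Two simulators provide inputs with the statistical structure the analysis
assumes:

- ``simulate_experiment`` emits raw two-channel spot tables for a 228-gene
  focused array (4 replicate spots per gene, 5 housekeeping controls) across
  the condition grid {LPS, four compound co-treatments} x {0.5, 2, 4, 12,
  48} h, with planted per-gene linear fold effects and multiplicative
  log-normal spot noise, plus the ground truth used to score recovery.
- ``simulate_network`` builds a signed signaling network with a planted
  master regulator wired to every query gene within a depth bound, plus
  distractor regulators wired to strict subsets and random filler edges.

``load_fixture`` exposes the packaged in-text tables (the three printed hit
tables, transcribed verbatim) and the synthetic figure-style networks.  The
network fixtures are constructed qualitative stand-ins, not transcriptions:
only their topology-level behaviour (which node is the unique bounded-depth
common denominator) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import keynode
from .array_processing import CATEGORIES, ValidationError

#: Treatment labels of the hybridized conditions (test channel contents);
#: each chip's control channel carries same-time vehicle.
LPS = "LPS"
COMPOUNDS = ("shikonin", "emodin", "cytopiloyne", "BF/S+L/Ep")
DEFAULT_TREATMENTS = (LPS,) + tuple(f"{c}+LPS" for c in COMPOUNDS)
DEFAULT_TIME_GRID = (0.5, 2.0, 4.0, 12.0, 48.0)

#: The five spotted housekeeping controls (alpha-tubulin, beta-2-
#: microglobulin, beta-actin, GAPDH, transferrin receptor).
HOUSEKEEPING_GENES = ("TUBA1A", "B2M", "ACTB", "GAPDH", "TFRC")


@dataclass
class ExperimentConfig:
    """Parameters of a simulated focused-array experiment.

    ``effects`` maps (gene_symbol, treatment, time_h) to the planted linear
    fold e > 0 of the test sample relative to same-time vehicle; unlisted
    combinations are null (e = 1).  ``noise_sigma`` is the standard
    deviation, in natural-log space, of the independent multiplicative
    log-normal noise applied to each channel of each spot.
    """

    n_genes: int = 228
    n_housekeeping: int = 5
    replicates: int = 4
    treatments: tuple = DEFAULT_TREATMENTS
    times: tuple = DEFAULT_TIME_GRID
    effects: dict = field(default_factory=dict)
    noise_sigma: float = 0.1
    base_intensity: float = 1000.0
    abundance_range: tuple = (0.05, 20.0)
    background: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if self.base_intensity <= 0 or self.background < 0:
            raise ValidationError("intensity scale must be positive")
        if self.replicates < 1:
            raise ValidationError("need at least one replicate spot per gene")
        if self.n_housekeeping < 1 or self.n_housekeeping >= self.n_genes:
            raise ValidationError("n_housekeeping must be in [1, n_genes)")
        lo, hi = self.abundance_range
        if not (0 < lo <= hi):
            raise ValidationError("abundance_range must be positive and ordered")
        for key, e in self.effects.items():
            if not e > 0:
                raise ValidationError(f"planted effect must be positive: {key} -> {e}")

    def gene_symbols(self) -> list[str]:
        hk = list(HOUSEKEEPING_GENES[: self.n_housekeeping])
        hk += [f"HK{i:02d}" for i in range(len(hk), self.n_housekeeping)]
        n_regular = self.n_genes - self.n_housekeeping
        return [f"G{i:03d}" for i in range(1, n_regular + 1)] + hk


@dataclass
class SimulatedExperiment:
    design: pd.DataFrame
    manifest: pd.DataFrame
    spot_tables: dict  # hybridization_id -> spot DataFrame
    truth: pd.DataFrame  # columns gene_symbol, treatment, time_h, effect
    config: ExperimentConfig


def simulate_experiment(config: ExperimentConfig) -> SimulatedExperiment:
    """Generate spot tables, manifest, design and ground truth.

    Per spot, the control channel expectation is base x gene abundance;
    the test channel expectation is that times the planted fold.  Both
    channels get independent log-normal noise, a constant additive
    background is recorded in both fg and bg columns (so background
    subtraction recovers the signal exactly), and housekeeping genes always
    carry e = 1.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_symbols()
    hk = set(genes[-config.n_housekeeping:])
    for (g, t, h), e in config.effects.items():
        if g in hk and e != 1:
            raise ValidationError(f"housekeeping gene {g} cannot carry an effect ({e})")

    categories = [c for c in CATEGORIES if c != "housekeeping"]
    design = pd.DataFrame(
        {
            "gene_symbol": genes,
            "gene_id": np.arange(1, len(genes) + 1) * 10,
            "category": [
                "housekeeping" if g in hk else categories[i % len(categories)]
                for i, g in enumerate(genes)
            ],
            "is_housekeeping": [g in hk for g in genes],
        }
    )
    lo, hi = config.abundance_range
    abundance = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    manifest_rows, spot_tables, truth_rows = [], {}, []
    n = len(genes)
    r = config.replicates
    for treatment in config.treatments:
        for time_h in config.times:
            hyb = f"{treatment}@{time_h:g}"
            manifest_rows.append(
                {
                    "hybridization_id": hyb,
                    "treatment": treatment,
                    "time_h": time_h,
                    "test_label": treatment,
                    "control_label": "vehicle",
                }
            )
            e = np.array(
                [config.effects.get((g, treatment, time_h), 1.0) for g in genes]
            )
            control_expect = np.repeat(config.base_intensity * abundance, r)
            test_expect = np.repeat(config.base_intensity * abundance * e, r)
            if config.noise_sigma > 0:
                control = control_expect * np.exp(
                    rng.normal(0.0, config.noise_sigma, size=n * r)
                )
                test = test_expect * np.exp(
                    rng.normal(0.0, config.noise_sigma, size=n * r)
                )
            else:
                control, test = control_expect, test_expect
            spot_tables[hyb] = pd.DataFrame(
                {
                    "probe_id": [
                        f"{g}_r{k}" for g in genes for k in range(1, r + 1)
                    ],
                    "gene_symbol": np.repeat(genes, r),
                    "replicate": np.tile(np.arange(1, r + 1), n),
                    "ch_control_fg": config.background + control,
                    "ch_control_bg": config.background,
                    "ch_test_fg": config.background + test,
                    "ch_test_bg": config.background,
                    "flag": "ok",
                }
            )
            for g, eg in zip(genes, e):
                truth_rows.append(
                    {"gene_symbol": g, "treatment": treatment, "time_h": time_h, "effect": eg}
                )
    return SimulatedExperiment(
        design=design,
        manifest=pd.DataFrame(manifest_rows),
        spot_tables=spot_tables,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_experiment(sim: SimulatedExperiment, out_dir) -> None:
    """Write design/manifest/spot tables (and truth) as TSV files."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    sim.design.to_csv(os.path.join(out_dir, "design.tsv"), sep="\t", index=False)
    sim.manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    sim.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    spots_dir = os.path.join(out_dir, "spots")
    os.makedirs(spots_dir, exist_ok=True)
    for hyb, table in sim.spot_tables.items():
        safe = hyb.replace("/", "_").replace("@", "_at_")
        table.to_csv(os.path.join(spots_dir, f"{safe}.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# planted-regulator networks
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Parameters of a planted master-regulator network.

    The planted regulator is wired to every query gene at a depth sampled in
    [1, max_depth], with the deepest wiring forced to exactly max_depth so
    that nodes upstream of the regulator overshoot the bound and cannot tie
    it at full coverage.  Distractors are wired to strict subsets of the
    query; filler edges are drawn among background nodes and downstream of
    query genes only, so they cannot create accidental full-coverage
    competitors.
    """

    n_nodes: int = 200
    n_query: int = 10
    max_depth: int = 4
    n_distractors: int = 3
    distractor_coverage: int = 7
    p_inhibit: float = 0.3
    n_random_edges: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if self.distractor_coverage >= self.n_query:
            raise ValidationError("distractor coverage must be a strict subset of the query")
        if not 0 <= self.p_inhibit <= 1:
            raise ValidationError("p_inhibit must be a probability")


def _wire(G, rng, source, gene, depth, p_inhibit, prefix, counter):
    """Connect source -> gene through depth-1 fresh intermediates; return net sign."""
    path = [source]
    for _ in range(depth - 1):
        node = f"{prefix}{next(counter):04d}"
        path.append(node)
    path.append(gene)
    net = 1
    for u, v in zip(path[:-1], path[1:]):
        sign = "inhibit" if rng.random() < p_inhibit else "activate"
        net *= keynode.SIGNS[sign]
        G.add_edge(u, v, sign=sign)
    return net


def simulate_network(config: NetworkConfig):
    """Build the planted network; returns (MultiDiGraph, truth dict).

    Truth records the planted regulator, each query gene's wired depth and
    its expected direction under the regulator's active-up state, and the
    distractors with their covered subsets.
    """
    rng = np.random.default_rng(config.seed)
    G = nx.MultiDiGraph()
    planted = "REG"
    query_genes = [f"Q{i:02d}" for i in range(1, config.n_query + 1)]
    G.add_node(planted)
    G.add_nodes_from(query_genes)

    counter = iter(range(10_000))
    depths = rng.integers(1, config.max_depth + 1, size=config.n_query)
    depths[rng.integers(0, config.n_query)] = config.max_depth
    directions = {}
    for gene, depth in zip(query_genes, depths):
        net = _wire(G, rng, planted, gene, int(depth), config.p_inhibit, "I", counter)
        directions[gene] = "up" if net == 1 else "down"

    distractors = {}
    for j in range(1, config.n_distractors + 1):
        name = f"D{j:02d}"
        subset = rng.choice(config.n_query, size=config.distractor_coverage, replace=False)
        covered = [query_genes[i] for i in sorted(subset)]
        for gene in covered:
            depth = int(rng.integers(1, config.max_depth + 1))
            _wire(G, rng, name, gene, depth, config.p_inhibit, "J", counter)
        distractors[name] = covered

    fillers = []
    while G.number_of_nodes() + len(fillers) < config.n_nodes:
        fillers.append(f"F{len(fillers):04d}")
    G.add_nodes_from(fillers)
    # background edges: among fillers, and from query genes down into fillers
    sources = fillers + query_genes
    for _ in range(config.n_random_edges):
        if not fillers:
            break
        u = sources[rng.integers(0, len(sources))]
        v = fillers[rng.integers(0, len(fillers))]
        if u == v:
            continue
        sign = "inhibit" if rng.random() < config.p_inhibit else "activate"
        G.add_edge(u, v, sign=sign)

    truth = {
        "regulator": planted,
        "depths": {g: int(d) for g, d in zip(query_genes, depths)},
        "directions": directions,
        "distractors": distractors,
    }
    return G, truth


# ---------------------------------------------------------------------------
# archetypal kinetic profiles
# ---------------------------------------------------------------------------

def simulate_mode_profiles(
    n_per_mode: int = 5,
    theta: float | None = None,
    times: tuple = (0.5, 2.0, 4.0, 12.0),
    margin: float = 1.5,
    seed: int = 0,
):
    """Noise-free log2 profiles embodying each regulation-mode definition.

    Responses are drawn at least ``margin`` x theta beyond the threshold and
    non-responses strictly inside it, so classification at that theta is
    unambiguous by construction.  Returns (profiles DataFrame, truth Series
    of RegulationMode).
    """
    from .kinetics import DEFAULT_THETA, RegulationMode

    if theta is None:
        theta = DEFAULT_THETA
    rng = np.random.default_rng(seed)
    early_t, delayed_t, up_t = 0.5, 2.0, 4.0
    for t in (early_t, delayed_t, up_t):
        if t not in times:
            raise ValidationError(f"times must include anchor {t}")

    def strong(sign):
        return sign * theta * rng.uniform(margin, 2 * margin)

    def none_level():
        return rng.uniform(-0.5 * theta, 0.5 * theta)

    rows, truth = {}, {}
    for mode in RegulationMode:
        for i in range(n_per_mode):
            name = f"{mode.value}_{i:02d}"
            prof = {t: none_level() for t in times}
            if mode is RegulationMode.EARLY_DOWN_THEN_UP:
                prof[early_t] = strong(-1)
                prof[up_t] = strong(+1)
            elif mode is RegulationMode.DELAYED_DOWN_THEN_UP:
                prof[early_t] = none_level()
                prof[delayed_t] = strong(-1)
                prof[up_t] = strong(+1)
            elif mode is RegulationMode.EARLY_NONE_THEN_UP:
                prof[early_t] = none_level()
                prof[delayed_t] = none_level()
                prof[up_t] = strong(+1)
            else:  # OTHER: no up-call at the up anchor
                prof[up_t] = none_level()
            rows[name] = prof
            truth[name] = mode
    profiles = pd.DataFrame.from_dict(rows, orient="index")[list(times)]
    return profiles, pd.Series(truth, name="mode")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

#: Times (hours) at which each transcribed hit table was read out.
TABLE_TIMES = {"table1": 0.5, "table2": 4.0, "table3": 12.0}

_NETWORK_FILES = {
    "fig5b_network": "fig5b_network.synthetic.tsv",
    "fig6a_network": "fig6a_network.synthetic.tsv",
    "fig6b_network": "fig6b_network.synthetic.tsv",
    "fig6c_network": "fig6c_network.synthetic.tsv",
    "fig7_network": "fig7_network.synthetic.tsv",
}

#: Query gene sets (with observed directions) that accompany each packaged
#: network fixture.
FIXTURE_QUERIES: Mapping[str, Mapping[str, str]] = {
    "fig5b_network": {
        g: "up"
        for g in (
            "CSF1", "IL5", "TNFSF14", "MADCAM1", "CD14", "TLR3", "IL1R2",
            "TNFRSF10D", "CCR1", "CCR8", "ITGAX", "CXCR4", "TBX21",
            "MAP2K4", "SHC1", "ADAMDEC1",
        )
    },
    "fig6a_network": {
        g: "down"
        for g in ("STAT1", "IL1B", "IL4", "NFATC3", "PTGS2", "TNF", "CCL4", "CCL8")
    },
    "fig6b_network": {
        g: "down"
        for g in ("NFATC3", "PTGS2", "LILRB4", "TAP2", "ETS1", "STAT1", "IL1B", "IL4")
    },
    "fig6c_network": {
        g: "down"
        for g in ("IL4", "IRF1", "GATA3", "NFATC3", "CCR2", "CXCR4", "BCL2", "PTGS2")
    },
    "fig7_network": {
        g: "down" for g in ("CCL2", "IGSF6", "CDH12", "SLAMF1", "CLEC1A")
    },
}

FIXTURE_NAMES = tuple(TABLE_TIMES) + tuple(_NETWORK_FILES)


@dataclass
class Fixture:
    name: str
    kind: str  # 'table' or 'network'
    payload: object  # DataFrame (table) or MultiDiGraph (network)
    time_h: float | None = None
    query: Mapping[str, str] | None = None


def _fixture_path(filename: str):
    return resources.files("phytoarray.fixtures") / filename


def load_fixture(name: str) -> Fixture:
    """Load a packaged fixture by name.

    Table payloads carry gene_symbol, gene_id, category and the four
    treatment ratio columns exactly as printed; network payloads are signed
    MultiDiGraphs with their companion query gene sets.
    """
    if name in TABLE_TIMES:
        with resources.as_file(_fixture_path(f"{name}.tsv")) as p:
            table = pd.read_csv(p, sep="\t")
        return Fixture(name, "table", table, time_h=TABLE_TIMES[name])
    if name in _NETWORK_FILES:
        with resources.as_file(_fixture_path(_NETWORK_FILES[name])) as p:
            G = keynode.load_network(p)
        return Fixture(name, "network", G, query=FIXTURE_QUERIES[name])
    raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}")


def table_ratio_matrix(name: str) -> pd.DataFrame:
    """A transcribed table as a treatment:LPS ratio matrix at its time point."""
    fx = load_fixture(name)
    if fx.kind != "table":
        raise KeyError(f"{name!r} is not a table fixture")
    matrix = fx.payload.set_index("gene_symbol")[["shikonin", "emodin", "cytopiloyne", "BF"]]
    matrix.columns = pd.MultiIndex.from_product(
        [matrix.columns, [fx.time_h]], names=["treatment", "time_h"]
    ).reorder_levels(["treatment", "time_h"])
    matrix.attrs["semantics"] = "treatment_vs_LPS"
    return matrix


def combined_table_profiles() -> pd.DataFrame:
    """All rows of the three transcribed tables as one treatments-comparable matrix.

    Rows are labelled ``gene@time`` (a gene printed in two tables contributes
    two rows, one per time point); columns are the four treatments; entries
    are linear treatment:LPS ratios.
    """
    frames = []
    for name, t in TABLE_TIMES.items():
        fx = load_fixture(name)
        sub = fx.payload[["gene_symbol", "shikonin", "emodin", "cytopiloyne", "BF"]].copy()
        sub.index = [f"{g}@{t:g}" for g in sub.pop("gene_symbol")]
        frames.append(sub)
    return pd.concat(frames, axis=0)
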