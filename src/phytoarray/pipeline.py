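"""End-to-end orchestration: ingest -> process -> filter -> modes ->
concordance -> cluster -> keynode, with a YAML run configuration, structured
logging and TSV report emission.

Every stage reads the previous stage's tabular outputs, so each is also
runnable in isolation through the CLI.  A run is fully determined by its
inputs and configuration; the run log echoes all parameters and the SHA-256
checksum of every input file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import array_processing as ap
from . import clustering, keynode, kinetics

logger = logging.getLogger(__name__)

STAGES = ("ingest", "process", "filter", "modes", "concordance", "cluster", "keynode")
#: Nonzero process exit status per failing stage.
STAGE_EXIT_CODES = {stage: i + 2 for i, stage in enumerate(STAGES)}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class RunConfig:
    """Validated flat run configuration (YAML-compatible)."""

    spots_dir: str
    manifest: str
    design: str
    out_dir: str
    network: str | None = None
    query_time_h: float = 4.0
    fold_threshold: float = 3.0
    theta: float = kinetics.DEFAULT_THETA
    metric: str = "euclidean_log2"
    max_depth: int = 4
    aggregate: str = "median"
    reference_gene: str = "ACTB"
    ratio_semantics: str = "vehicle_ref"
    reference_treatment: str = "cytopiloyne"
    seed: int = 0
    times: tuple = (0.5, 2.0, 4.0, 12.0, 48.0)

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.metric not in clustering.METRICS:
            raise ValueError(f"metric must be one of {clustering.METRICS}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")
        if self.ratio_semantics not in ("vehicle_ref", "lps_ref"):
            raise ValueError("ratio_semantics must be 'vehicle_ref' or 'lps_ref'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "times" in raw:
            raw["times"] = tuple(float(t) for t in raw["times"])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of output paths.

    Input files are checked before any output is written, so a missing input
    aborts cleanly without partial results.
    """
    # ---- ingest ----------------------------------------------------------
    inputs = {"manifest": config.manifest, "design": config.design}
    if config.network:
        inputs["network"] = config.network
    for name, path in inputs.items():
        if not os.path.exists(path):
            raise StageError("ingest", f"missing input file {name!r}: {path}")
    if not os.path.isdir(config.spots_dir):
        raise StageError("ingest", f"missing spot-table directory: {config.spots_dir}")
    try:
        design = ap.read_design(config.design)
        manifest = ap.read_manifest(config.manifest)
        spot_files = sorted(
            f for f in os.listdir(config.spots_dir) if f.endswith(".tsv")
        )
        spot_tables = {}
        by_hyb = {}
        for f in spot_files:
            by_hyb[os.path.splitext(f)[0]] = os.path.join(config.spots_dir, f)
        for row in manifest.itertuples(index=False):
            safe = row.hybridization_id.replace("/", "_").replace("@", "_at_")
            if safe not in by_hyb:
                raise ap.ValidationError(
                    f"no spot table for hybridization {row.hybridization_id!r}"
                )
            spot_tables[row.hybridization_id] = ap.read_spot_table(by_hyb[safe])
    except ap.ValidationError as err:
        raise StageError("ingest", str(err)) from err

    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    paths: dict[str, str] = {}

    # ---- process ---------------------------------------------------------
    try:
        matrix = ap.process_experiment(
            spot_tables, manifest, design,
            aggregate=config.aggregate, reference_gene=config.reference_gene,
        )
        if config.ratio_semantics == "vehicle_ref":
            vs_lps = ap.treatment_vs_lps(matrix)
        else:
            # chips were hybridized against LPS directly: drop any LPS column
            keep = [c for c in matrix.columns if c[0] != "LPS"]
            vs_lps = matrix[keep]
        ap.write_ratio_matrix(matrix, out("ratios_vs_vehicle.tsv"))
        ap.write_ratio_matrix(vs_lps, out("ratios_vs_lps.tsv"))
        paths["ratios_vs_vehicle"] = out("ratios_vs_vehicle.tsv")
        paths["ratios_vs_lps"] = out("ratios_vs_lps.tsv")
    except (ap.ValidationError, ValueError) as err:
        raise StageError("process", str(err)) from err

    # ---- filter ----------------------------------------------------------
    try:
        hit_frames = []
        for time_h in config.times:
            if time_h not in vs_lps.columns.get_level_values("time_h"):
                continue
            hits = ap.filter_fold_change(
                vs_lps, threshold=config.fold_threshold,
                direction="both", time_h=time_h, design=design,
            )
            hit_frames.append(hits)
        hit_frames = [h for h in hit_frames if not h.empty]
        all_hits = (
            pd.concat(hit_frames, ignore_index=True) if hit_frames else pd.DataFrame()
        )
        all_hits.to_csv(out("hits.tsv"), sep="\t", index=False)
        paths["hits"] = out("hits.tsv")
    except (ap.ValidationError, ValueError) as err:
        raise StageError("filter", str(err)) from err

    # ---- modes -----------------------------------------------------------
    try:
        treatments = sorted(set(vs_lps.columns.get_level_values("treatment")))
        modes_by_treatment = {}
        mode_rows = []
        for treatment in treatments:
            profiles = kinetics.build_profiles(vs_lps, treatment)
            modes = kinetics.classify_modes(profiles, theta=config.theta)
            modes_by_treatment[treatment] = modes.to_dict()
            for gene, mode in modes.items():
                mode_rows.append(
                    {"gene_symbol": gene, "treatment": treatment, "mode": mode.value}
                )
        pd.DataFrame(mode_rows).to_csv(out("modes.tsv"), sep="\t", index=False)
        paths["modes"] = out("modes.tsv")
    except ValueError as err:
        raise StageError("modes", str(err)) from err

    # ---- concordance -----------------------------------------------------
    try:
        if config.reference_treatment in modes_by_treatment:
            conc = kinetics.concordance_table(
                modes_by_treatment, config.reference_treatment
            )
        else:
            logger.warning(
                "reference treatment %r absent; skipping concordance",
                config.reference_treatment,
            )
            conc = pd.DataFrame()
        conc.to_csv(out("concordance.tsv"), sep="\t", index=False)
        paths["concordance"] = out("concordance.tsv")
    except ValueError as err:
        raise StageError("concordance", str(err)) from err

    # ---- cluster ---------------------------------------------------------
    try:
        complete = vs_lps.dropna(axis=0, how="any")
        treatment_matrix = pd.DataFrame(
            {t: complete.xs(t, axis=1, level="treatment").to_numpy().ravel()
             for t in treatments},
        ).T
        linkage_t = clustering.upgma(
            clustering.distance_matrix(treatment_matrix, config.metric)
        )
        with open(out("treatments.nwk"), "w") as fh:
            fh.write(clustering.to_newick(linkage_t) + "\n")
        paths["treatments_newick"] = out("treatments.nwk")
        if complete.shape[0] >= 2:
            linkage_g = clustering.upgma(
                clustering.distance_matrix(complete, config.metric)
            )
            with open(out("genes.nwk"), "w") as fh:
                fh.write(clustering.to_newick(linkage_g) + "\n")
            pd.DataFrame(
                linkage_g.records,
                columns=["child_a", "child_b", "merge_distance", "size"],
            ).to_csv(out("genes_linkage.tsv"), sep="\t", index=False)
            paths["genes_newick"] = out("genes.nwk")
    except ValueError as err:
        raise StageError("cluster", str(err)) from err

    # ---- keynode ---------------------------------------------------------
    try:
        if config.network:
            G = keynode.load_network(config.network)
            q_hits = all_hits[all_hits["time_h"] == config.query_time_h]
            query = dict(zip(q_hits["gene_symbol"], q_hits["direction"]))
            if query:
                results = keynode.find_key_nodes(
                    G, query, max_depth=config.max_depth, require_full_coverage=False
                )
                pd.DataFrame([r.to_dict() for r in results]).to_csv(
                    out("keynodes.tsv"), sep="\t", index=False
                )
            else:
                logger.info("no hit genes at %g h; writing empty key-node report",
                            config.query_time_h)
                pd.DataFrame().to_csv(out("keynodes.tsv"), sep="\t", index=False)
            paths["keynodes"] = out("keynodes.tsv")
    except (ValueError, keynode.NetworkParseError) as err:
        raise StageError("keynode", str(err)) from err

    # ---- run log ---------------------------------------------------------
    with open(out("run_log.txt"), "w") as fh:
        fh.write("parameters:\n")
        for f in dataclasses.fields(config):
            fh.write(f"  {f.name}: {getattr(config, f.name)}\n")
        fh.write("input checksums (sha256):\n")
        for name, path in sorted(inputs.items()):
            fh.write(f"  {name}: {_sha256(path)}\n")
        for row in manifest.itertuples(index=False):
            hyb = row.hybridization_id
            safe = hyb.replace("/", "_").replace("@", "_at_")
            fh.write(f"  spots/{safe}: {_sha256(os.path.join(config.spots_dir, safe + '.tsv'))}\n")
    paths["run_log"] = out("run_log.txt")
    return paths
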