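"""End-to-end orchestration: generate -> profile -> consensus -> cluster ->
composition -> swim-up statistics, with seed bookkeeping and a manifest.

All intermediates are plain files (CSV/SVG/JSON) so any stage can be
re-run or inspected independently. A single pipeline seed is split
deterministically into per-stage seeds which are logged in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import clustering as clu
from . import morphometry as morph
from . import stats as st
from .geometry import Outline
from .synthetic import (NucleusRecord, PopulationSpec, SwimUpModelSpec,
                        generate_population, generate_swimup_counts,
                        population_table)

__all__ = ["RunConfig", "run_pipeline", "derive_stage_seeds",
           "build_measured_population", "outlines_to_frame",
           "outlines_from_frame"]

STAGES = ("generate", "profile", "consensus", "cluster", "swimup")


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 0
    genotypes: tuple[str, ...] = ("WT", "YQDEL")
    n_cells: int = 500
    outline_points: int = 200
    window_fraction: float = 0.05
    profile_points: int = 100
    perplexity: float = 100.0
    tsne_max_iter: int = 1000
    cluster_k: int | None = 2
    cluster_on: str = "profiles"      # "profiles" or "tsne"
    swimup_n_males: int = 10
    swimup_cells_per_fraction: int = 400
    out_dir: str = "pipeline_out"

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["genotypes"] = list(self.genotypes)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = cls.__dataclass_fields__
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "genotypes" in data:
            data["genotypes"] = tuple(data["genotypes"])
        return cls(**data)


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministically split one pipeline seed into per-stage seeds."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2 ** 31))
            for stage, c in zip(STAGES, children)}


def build_measured_population(genotype: str, n_cells: int, seed: int,
                              outline_points: int = 200,
                              window_fraction: float = 0.05,
                              profile_points: int = 100
                              ) -> list[NucleusRecord]:
    """Generate a population and fill profiles and morphometrics."""
    from .segmentation import smooth_resample

    records = generate_population(
        PopulationSpec(genotype=genotype, n_cells=n_cells, seed=seed))
    for rec in records:
        rec.outline = smooth_resample(rec.outline, outline_points,
                                      smooth_window=0.0)
    morph.measure_records(records, window_fraction, profile_points)
    return records


def outlines_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.outline is None:
            continue
        for i, (x, y) in enumerate(r.outline.vertices):
            rows.append({"id": r.cell_id, "vertex": i, "x": x, "y": y})
    return pd.DataFrame(rows)


def outlines_from_frame(frame: pd.DataFrame) -> dict[str, Outline]:
    out = {}
    for cell_id, sub in frame.groupby("id", sort=False):
        sub = sub.sort_values("vertex")
        out[str(cell_id)] = Outline(sub[["x", "y"]].to_numpy(float))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "stage_seeds": seeds,
                      "outputs": {}, "summary": {}}
    stage = "generate"
    try:
        # --- generate + profile -------------------------------------------
        populations: dict[str, list[NucleusRecord]] = {}
        for g_i, genotype in enumerate(config.genotypes):
            populations[genotype] = build_measured_population(
                genotype, config.n_cells, seeds["generate"] + g_i,
                config.outline_points, config.window_fraction,
                config.profile_points)
        all_records = [r for recs in populations.values() for r in recs]
        population_table(all_records).to_csv(out / "population.csv",
                                             index=False)
        stage = "profile"
        profiles_frame = morph.profiles_to_frame(all_records)
        profiles_frame.to_csv(out / "profiles.csv", index=False)
        xy_tests = morph.compare_xy(all_records)
        xy_tests.to_csv(out / "xy_comparison.csv", index=False)

        # --- consensus per genotype ---------------------------------------
        stage = "consensus"
        consensus_rows = []
        reference_profile = None
        for genotype, recs in populations.items():
            outlines = [r.outline for r in recs]
            apexes = [int(round(morph.anchored_profile(
                o, config.window_fraction)[1] * len(o))) % len(o)
                for o in outlines]
            aligned = cns.align_outlines(outlines, apexes)
            shape = cns.consensus_shape(aligned)
            for i, (x, y) in enumerate(shape.mean_outline.vertices):
                consensus_rows.append({"genotype": genotype, "vertex": i,
                                       "x": x, "y": y,
                                       "radial_iqr": shape.envelope[i]})
            (out / f"consensus_{genotype}.svg").write_text(
                f'<svg xmlns="http://www.w3.org/2000/svg">'
                f'<path d="{cns.consensus_to_svg_path(shape)}" '
                f'fill="none" stroke="black"/></svg>')
            if genotype == "WT":
                reference_profile = np.mean(
                    [r.profile for r in recs], axis=0)
        pd.DataFrame(consensus_rows).to_csv(out / "consensus.csv",
                                            index=False)

        # --- clustering + composition -------------------------------------
        stage = "cluster"
        profile_matrix = np.array([r.profile for r in all_records])
        sex = np.array([r.sex for r in all_records])
        genotype_arr = np.array([r.genotype for r in all_records])
        if config.cluster_on == "tsne":
            features = clu.embed_profiles(
                profile_matrix, config.perplexity, config.tsne_max_iter,
                seeds["cluster"])
            pd.DataFrame({"id": [r.cell_id for r in all_records],
                          "x": features[:, 0], "y": features[:, 1]}
                         ).to_csv(out / "embedding.csv", index=False)
        else:
            features = profile_matrix
        assignment = clu.cluster_profiles(
            features, k=config.cluster_k, feature_space=config.cluster_on,
            seed=seeds["cluster"])
        for rec, lab in zip(all_records, assignment.labels):
            rec.cluster = int(lab)
        pd.DataFrame({"id": [r.cell_id for r in all_records],
                      "cluster": assignment.labels}
                     ).to_csv(out / "clusters.csv", index=False)
        composition = clu.cluster_sex_composition(assignment, sex)
        composition.to_csv(out / "cluster_composition.csv", index=False)
        ranking = clu.rank_clusters_by_reference(
            assignment, profile_matrix, reference_profile)
        ranking.to_csv(out / "cluster_ranking.csv", index=False)
        # normal-cluster X% among mutant cells only (the drive readout)
        mutant = genotype_arr != "WT"
        mutant_comp = {}
        if mutant.any():
            sub_assign = clu.ClusterAssignment(
                labels=assignment.labels[mutant], k=assignment.k,
                feature_space=assignment.feature_space)
            mutant_comp_df = clu.cluster_sex_composition(
                sub_assign, sex[mutant])
            normal_cluster = int(ranking.iloc[0]["cluster"])
            row = mutant_comp_df[mutant_comp_df.cluster == normal_cluster]
            if len(row):
                mutant_comp = {
                    "normal_cluster": normal_cluster,
                    "x_percent": float(row.iloc[0]["x_proportion"] * 100),
                    "se_percent": float(row.iloc[0]["se_proportion"] * 100)}
        manifest["summary"]["normal_cluster_composition"] = mutant_comp

        # --- swim-up statistics -------------------------------------------
        stage = "swimup"
        swim_spec = SwimUpModelSpec(
            n_males=config.swimup_n_males,
            cells_per_fraction=config.swimup_cells_per_fraction,
            seed=seeds["swimup"])
        swim = generate_swimup_counts(swim_spec)
        swim.to_csv(out / "swimup_counts.csv", index=False)
        report = st.swimup_report(swim)
        report.to_csv(out / "swimup_report.csv", index=False)
        full = st.betareg_fit(swim)
        reduced = st.betareg_fit(
            swim, formula="x_prop ~ C(genotype) * C(state) + segment")
        chi2, df_lrt, p_lrt = st.likelihood_ratio_test(full, reduced)
        manifest["summary"]["swimup"] = {
            "betareg_llf": full.llf, "betareg_phi": full.phi,
            "interaction_lrt_chi2": chi2, "interaction_lrt_df": df_lrt,
            "interaction_lrt_p": p_lrt}
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.iterdir())
                           if p.suffix in (".csv", ".svg")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
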