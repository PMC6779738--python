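"""Configuration-driven orchestration of the full temporal MSA analysis.

A :class:`RunConfig` (YAML) names the input files, partition definitions and
sampler settings; :func:`run_all` executes the stages in analysis order —

    partitions -> diversity -> divergence (phi-ST / Mantel)
    -> mixed stock analysis per partition x size class -> dC
    -> demography -> correlations/regressions

writing each stage's outputs (CSV/JSON) under the output directory before
the next begins, and maintaining a machine-readable run manifest with the
config hash, per-stage status, seeds, orphan/dropped tallies and MCMC
convergence flags. A failure in one MSA cell is recorded and does not abort
independent cells. Re-running an identical config reproduces identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConvergenceError, DataError, EmptyPartitionError, UndefinedStatisticError
from .haplotypes import HaplotypeCounts, HaplotypePanel, ObservationTable, expand_recaptures, partition
from .mixed_stock import (
    BaselineSet,
    aggregate_regions,
    delta_c,
    gelman_rubin,
    gibbs_msa,
    prepare_mixture,
    summarize,
)
from .popgen import (
    haplotype_diversity,
    mantel_test,
    nucleotide_diversity,
    pairwise_differences,
    pairwise_phi_matrix,
    phi_st_permutation_test,
    year_distance_matrix,
)
from .demography import (
    NestSeries,
    growth_rate_from_nests,
    load_demographic_table,
    logistic_increase_model,
    reproductive_output,
    spearman,
    stepwise_ols,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; all paths resolved, all seeds explicit."""

    observations: Path
    baselines: Path
    output_dir: Path
    seed: int
    panel: Path | None = None
    nest_series: Path | None = None
    demography: Path | None = None
    early_years: tuple[int, ...] = (2006, 2007)
    late_years: tuple[int, ...] = (2015, 2016)
    scl_cutoffs: tuple[float | None, ...] = (75.0, 50.0)
    year_range: tuple[int, int] = (1990, 2100)
    n_permutations: int = 1000
    msa_n_iter: int = 4000
    msa_burn_in: int = 2000
    msa_n_chains: int = 3
    save_draws: bool = False
    raw: Mapping[str, Any] = field(default_factory=dict, compare=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        if "seed" not in raw:
            raise DataError("config must set an explicit seed")
        inputs = raw.get("inputs", {})

        def resolve(key: str, required: bool = False) -> Path | None:
            value = inputs.get(key)
            if value is None:
                if required:
                    raise DataError(f"config missing required input {key!r}")
                return None
            p = (base / value).resolve()
            if not p.exists():
                raise DataError(f"input file for {key!r} does not exist: {p}")
            return p

        parts = raw.get("partitions", {})
        msa = raw.get("msa", {})
        popgen = raw.get("popgen", {})
        cutoffs = tuple(
            None if c in (None, "none") else float(c)
            for c in parts.get("scl_cutoffs", [75.0, 50.0])
        )
        return cls(
            observations=resolve("observations", required=True),
            baselines=resolve("baselines", required=True),
            panel=resolve("panel"),
            nest_series=resolve("nest_series"),
            demography=resolve("demography"),
            output_dir=(base / raw.get("output_dir", "out")).resolve(),
            seed=int(raw["seed"]),
            early_years=tuple(int(y) for y in parts.get("early_years", [2006, 2007])),
            late_years=tuple(int(y) for y in parts.get("late_years", [2015, 2016])),
            scl_cutoffs=cutoffs,
            year_range=tuple(parts.get("year_range", [1990, 2100])),
            n_permutations=int(popgen.get("n_permutations", 1000)),
            msa_n_iter=int(msa.get("n_iter", 4000)),
            msa_burn_in=int(msa.get("burn_in", 2000)),
            msa_n_chains=int(msa.get("n_chains", 3)),
            save_draws=bool(raw.get("save_draws", False)),
            raw=raw,
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _cutoff_tag(cutoff: float | None) -> str:
    return "all" if cutoff is None else f"lt{cutoff:g}"


class Manifest:
    """Run manifest written before and finalized after each stage."""

    def __init__(self, config: RunConfig) -> None:
        self.path = config.output_dir / "manifest.json"
        self.data: dict[str, Any] = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
            "tallies": {},
            "convergence": {},
        }

    def stage(self, name: str, status: str, **info: Any) -> None:
        self.data["stages"][name] = {"status": status, **info}
        self.write()

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every analysis stage; return the in-memory result bundle."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    bundle: dict[str, Any] = {"config": config, "manifest": manifest}
    rng_seed = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["popgen", "msa_early", "msa_late"], rng_seed.spawn(3)
        )
    }
    manifest.data["stage_seeds"] = stage_seeds

    # --- load & partition ---------------------------------------------------
    manifest.stage("partitions", "running")
    observations = expand_recaptures(
        ObservationTable.from_csv(config.observations, year_range=config.year_range)
    )
    baselines = BaselineSet.from_csv(config.baselines)
    n_individuals = len(observations.individuals)
    manifest.data["tallies"]["records"] = len(observations)
    manifest.data["tallies"]["individuals"] = n_individuals
    manifest.data["tallies"]["recapture_events"] = len(observations) - n_individuals

    partitions: dict[tuple[str, str], HaplotypeCounts] = {}
    part_dir = out / "partitions"
    part_dir.mkdir(exist_ok=True)
    for time_label, years in (("early", config.early_years), ("late", config.late_years)):
        for cutoff in config.scl_cutoffs:
            tag = _cutoff_tag(cutoff)
            try:
                counts = partition(
                    observations, years, cutoff, label=f"{time_label}_{tag}"
                )
            except EmptyPartitionError as exc:
                manifest.stage("partitions", "partial", error=str(exc))
                continue
            partitions[(time_label, tag)] = counts
            counts.to_csv(part_dir / f"{counts.label}.csv")
    bundle["partitions"] = partitions
    manifest.stage("partitions", "done", n=len(partitions))

    # --- diversity ----------------------------------------------------------
    panel = HaplotypePanel.from_fasta(config.panel) if config.panel else None
    distances = pairwise_differences(panel) if panel else None
    manifest.stage("diversity", "running")
    rows = []
    for (time_label, tag), counts in partitions.items():
        row = {
            "partition": counts.label,
            "n": counts.n,
            "n_haplotypes": len(counts.counts),
            "h": haplotype_diversity(counts) if counts.n >= 2 else np.nan,
        }
        if distances is not None and panel is not None:
            row["pi"] = nucleotide_diversity(counts, distances, panel.length)
        rows.append(row)
    diversity = pd.DataFrame(rows)
    diversity.to_csv(out / "diversity.csv", index=False)
    bundle["diversity"] = diversity
    manifest.stage("diversity", "done")

    # --- divergence: phi-ST early vs late, per-year Mantel -------------------
    if distances is None:
        manifest.stage("divergence", "skipped", reason="no haplotype panel configured")
    else:
        manifest.stage("divergence", "running")
        divergence: dict[str, Any] = {}
        for cutoff in config.scl_cutoffs:
            tag = _cutoff_tag(cutoff)
            pair = partitions.get(("early", tag)), partitions.get(("late", tag))
            if None in pair:
                continue
            try:
                res = phi_st_permutation_test(
                    pair[0], pair[1], distances,
                    n_perm=config.n_permutations, seed=stage_seeds["popgen"],
                )
                divergence[tag] = {
                    "phi_st": res.phi_st,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            except UndefinedStatisticError as exc:
                divergence[tag] = {"error": str(exc)}
            # per-year matrix + Mantel vs time
            yearly = []
            for year in sorted({r.year for r in observations.records}):
                try:
                    yearly.append(partition(observations, [year], cutoff))
                except EmptyPartitionError:
                    continue
            if len(yearly) >= 3:
                phi_mat = pairwise_phi_matrix(yearly, distances)
                phi_mat.to_csv(out / f"phi_matrix_{tag}.csv")
                years_map = {
                    p.label: int(p.label.split("_")[0].split("-")[0]) for p in yearly
                }
                time_mat = year_distance_matrix(years_map)
                try:
                    mres = mantel_test(
                        phi_mat, time_mat,
                        n_perm=config.n_permutations, seed=stage_seeds["popgen"],
                    )
                    divergence[f"mantel_{tag}"] = {
                        "r": mres.r,
                        "r_squared": mres.r_squared,
                        "p_value": mres.p_value,
                    }
                except UndefinedStatisticError as exc:
                    divergence[f"mantel_{tag}"] = {"error": str(exc)}
        with open(out / "divergence.json", "w") as fh:
            json.dump(divergence, fh, indent=2, sort_keys=True)
        bundle["divergence"] = divergence
        manifest.stage("divergence", "done")

    # --- mixed stock analysis per partition x cutoff -------------------------
    manifest.stage("msa", "running")
    msa_dir = out / "msa"
    msa_dir.mkdir(exist_ok=True)
    summaries: dict[tuple[str, str, str], Any] = {}
    for (time_label, tag), counts in partitions.items():
        cell = f"{time_label}_{tag}"
        try:
            mixture = prepare_mixture(counts, baselines)
            manifest.data["tallies"][f"orphans_{cell}"] = mixture.n_orphans
            draws = gibbs_msa(
                mixture,
                baselines,
                n_iter=config.msa_n_iter,
                burn_in=config.msa_burn_in,
                n_chains=config.msa_n_chains,
                seed=stage_seeds[f"msa_{time_label}"],
            )
            diag = gelman_rubin(draws)
            manifest.data["convergence"][cell] = {
                "max_rhat": float(np.nanmax(diag.rhat)),
                "converged": diag.converged,
            }
            stock_summary = summarize(draws, check_convergence=False)
            region_summary = aggregate_regions(
                draws, baselines.regions, check_convergence=False
            )
            stock_summary.to_frame().to_csv(msa_dir / f"{cell}_stocks.csv", index=False)
            region_summary.to_frame().to_csv(msa_dir / f"{cell}_regions.csv", index=False)
            if config.save_draws:
                draws.to_csv(msa_dir / f"{cell}_draws.csv")
            summaries[(time_label, tag, "stock")] = stock_summary
            summaries[(time_label, tag, "region")] = region_summary
        except (DataError, ConvergenceError) as exc:
            manifest.data["stages"].setdefault("msa_errors", {})
            manifest.stage("msa", "running", **{f"error_{cell}": str(exc)})
            logger.error("MSA cell %s failed: %s", cell, exc)
    bundle["msa"] = summaries
    manifest.stage("msa", "done", cells=len(summaries) // 2)

    # --- dC ------------------------------------------------------------------
    manifest.stage("delta_c", "running")
    dc_rows = []
    for tag in {t for (_, t) in partitions}:
        for level in ("stock", "region"):
            early = summaries.get(("early", tag, level))
            late = summaries.get(("late", tag, level))
            if early is None or late is None:
                continue
            dc = delta_c(early, late)
            for unit, value in dc.items():
                dc_rows.append(
                    {"unit": unit, "level": level, "cutoff": tag, "delta_c": value}
                )
    dc_table = pd.DataFrame(dc_rows)
    dc_table.to_csv(out / "delta_c.csv", index=False)
    bundle["delta_c"] = dc_table
    manifest.stage("delta_c", "done")

    # --- demography ----------------------------------------------------------
    manifest.stage("demography", "running")
    growth_rows = []
    if config.nest_series:
        for name, series in NestSeries.many_from_csv(config.nest_series).items():
            try:
                growth_rows.append({"rookery": name, "r": growth_rate_from_nests(series)})
            except UndefinedStatisticError as exc:
                growth_rows.append({"rookery": name, "r": np.nan, "note": str(exc)})
        pd.DataFrame(growth_rows).to_csv(out / "growth.csv", index=False)
    demo = load_demographic_table(config.demography) if config.demography else None
    if demo is not None:
        demo = demo.copy()
        demo["Nr_recomputed"] = [
            reproductive_output(n, r) for n, r in zip(demo["N"], demo["r"])
        ]
        demo.to_csv(out / "demography.csv", index=False)
    bundle["demography"] = demo
    bundle["growth"] = pd.DataFrame(growth_rows)
    manifest.stage("demography", "done")

    # --- correlations ---------------------------------------------------------
    if demo is None or dc_table.empty:
        manifest.stage("correlations", "skipped", reason="needs demography table and dC")
    else:
        manifest.stage("correlations", "running")
        correlations: dict[str, Any] = {}
        regions = demo[demo["region"] == "-"]
        rookeries = demo[demo["region"] != "-"]
        for tag in sorted({t for (_, t) in partitions}):
            sub = dc_table[(dc_table["level"] == "region") & (dc_table["cutoff"] == tag)]
            merged = regions.merge(sub, left_on="unit", right_on="unit")
            if len(merged) >= 3:
                try:
                    sres = spearman(merged["delta_c"], merged["Nr"])
                    correlations[f"spearman_region_{tag}"] = {
                        "rho": sres.rho, "p_value": sres.p_value, "exact": sres.exact,
                        "n": len(merged),
                    }
                except UndefinedStatisticError as exc:
                    correlations[f"spearman_region_{tag}"] = {"error": str(exc)}
            sub_r = dc_table[(dc_table["level"] == "stock") & (dc_table["cutoff"] == tag)]
            merged_r = rookeries.merge(sub_r, left_on="unit", right_on="unit")
            if len(merged_r) >= 4:
                dc_map = dict(zip(merged_r["unit"], merged_r["delta_c"]))
                nr_map = dict(zip(merged_r["unit"], merged_r["Nr"]))
                try:
                    rep = logistic_increase_model(dc_map, nr_map)
                    correlations[f"logistic_rookery_{tag}"] = rep.to_json_dict()
                except DataError as exc:
                    correlations[f"logistic_rookery_{tag}"] = {"skipped": str(exc)}
                # stepwise model of late mean contribution on ln N, D, Nr
                late_sum = summaries.get(("late", tag, "stock"))
                if late_sum is not None:
                    contrib = late_sum.as_dict()
                    common = [u for u in merged_r["unit"] if u in contrib]
                    if len(common) > 4:
                        dsub = merged_r.set_index("unit").loc[common]
                        try:
                            rep = stepwise_ols(
                                [contrib[u] for u in common],
                                {
                                    "ln_N": np.log(dsub["N"].to_numpy(dtype=float)),
                                    "D": dsub["D_km"].to_numpy(dtype=float),
                                    "Nr": dsub["Nr"].to_numpy(dtype=float),
                                },
                            )
                            correlations[f"stepwise_late_{tag}"] = rep.to_json_dict()
                        except DataError as exc:
                            correlations[f"stepwise_late_{tag}"] = {"skipped": str(exc)}
        with open(out / "correlations.json", "w") as fh:
            json.dump(correlations, fh, indent=2, sort_keys=True)
        bundle["correlations"] = correlations
        manifest.stage("correlations", "done")

    manifest.write()
    return bundle


def report(bundle: Mapping[str, Any]) -> str:
    """Human-readable summary of a completed (or partial) run bundle."""
    lines: list[str] = ["stockshift run report", "=" * 60]
    diversity = bundle.get("diversity")
    if diversity is not None and len(diversity):
        lines += ["", "Diversity per partition:", diversity.to_string(index=False)]
    else:
        lines += ["", "Diversity: [not computed]"]
    divergence = bundle.get("divergence")
    if divergence:
        lines += ["", "Temporal divergence:"]
        for key, val in sorted(divergence.items()):
            lines.append(f"  {key}: {json.dumps(val, sort_keys=True)}")
    msa = bundle.get("msa", {})
    if msa:
        lines += ["", "Mixed stock contributions (posterior mean [95% CI]):"]
        for (time_label, tag, level), summ in sorted(msa.items()):
            if level != "region":
                continue
            parts = ", ".join(
                f"{u}={m:.2f}[{lo:.2f},{hi:.2f}]"
                for u, m, lo, hi in zip(summ.labels, summ.mean, summ.lower, summ.upper)
            )
            lines.append(f"  {time_label}/{tag}: {parts}")
    else:
        lines += ["", "Mixed stock analysis: [not estimated]"]
    dc = bundle.get("delta_c")
    if dc is not None and len(dc):
        lines += ["", "Temporal recruitment change (dC, region level):"]
        sub = dc[dc["level"] == "region"]
        lines.append(sub.pivot(index="unit", columns="cutoff", values="delta_c").to_string())
    demo = bundle.get("demography")
    if demo is not None:
        lines += ["", "Demographic table (regions):"]
        lines.append(demo[demo["region"] == "-"].to_string(index=False))
    correlations = bundle.get("correlations")
    if correlations:
        lines += ["", "Recovery vs recruitment statistics:"]
        for key, val in sorted(correlations.items()):
            lines.append(f"  {key}: {json.dumps(val, sort_keys=True)}")
    manifest = bundle.get("manifest")
    if manifest is not None:
        missing = [
            s for s, info in manifest.data["stages"].items() if info.get("status") != "done"
        ]
        if missing:
            lines += ["", f"Stages not completed: {missing}"]
    return "\n".join(lines)
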