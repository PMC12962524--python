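"""End-to-end emulation runs: simulate -> impute -> fit -> effects -> clusters.

One master seed fans out to per-stage seeds through a fixed counter-based
derivation (stage index into a seed sequence), so adding a stage never
perturbs the seeds of existing ones and any single stage can be re-run in
isolation.  All artifacts are plain CSV/JSON/markdown carrying the master
seed and package version; a run is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import design_matrix
from .ensemble import cv_stack, default_library, glm_library
from .gcomputation import (
    EffectEstimate,
    baseline_table,
    compute_ite,
    counterfactual_predict,
    estimate_effects,
    evalue_rr,
    nnt_from_rd,
    propensity_overlap,
)
from .generate import (
    GenerationConfig,
    apply_eligibility,
    default_config,
    generate_cohort,
    impose_missingness,
    randomized_config,
    recovery_config,
)
from .heterogeneity import (
    beale_select_k,
    cluster_cate,
    cluster_profile,
    covariate_importance,
    jitter_standardize,
    sensitivity_thresholds,
    ward_cluster,
)
from .impute import rf_impute
from .schema import TREATMENT_COL, default_schema

# counter-based seed fan-out: stage name -> fixed counter
_STAGE_COUNTERS = {
    "generate": 0,
    "missingness": 1,
    "impute": 2,
    "ensemble": 3,
    "effects": 4,
    "overlap": 5,
    "heterogeneity": 6,
}

OUTCOME_COLUMNS = {"binary": "y_uncontrolled", "delta_sbp": "delta_sbp", "delta_dbp": "delta_dbp"}
GENERATORS = {"default": default_config, "recovery": recovery_config, "randomized": randomized_config}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed), _STAGE_COUNTERS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full emulation run."""

    n_total: int = 3092
    generator: str = "default"  # default | recovery | randomized
    eligibility_days: tuple[int, int] = (275, 455)
    outcome: str = "binary"  # binary | delta_sbp | delta_dbp
    library: str = "default"  # default | glm
    V: int = 10
    n_boot: int = 200
    fast_boot: bool = True
    alpha: float = 0.01
    thresholds: tuple[float, ...] = (0.20, 0.25, 0.30)
    noise_sd: float | None = None  # None -> 1% of ITE spread
    impute_trees: int = 100
    impute_max_iter: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.library not in ("default", "glm"):
            raise ValueError(f"unknown library {self.library!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eligibility_days"] = list(d["eligibility_days"])
        d["thresholds"] = list(d["thresholds"])
        return d

    def make_library(self):
        return default_library() if self.library == "default" else glm_library()


def _meta(seed: int) -> dict:
    return {"package": "hte-emulate", "version": __version__, "master_seed": int(seed)}


def _write_json(path: Path, obj: dict, seed: int) -> None:
    obj = {"meta": _meta(seed), **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_csv(path: Path, df: pd.DataFrame, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hte-emulate v{__version__} master_seed={seed}\n")
        df.to_csv(fh, index=False)


def format_effect(estimate: EffectEstimate, style: str | None = None) -> str:
    """Display formatting matching the reporting conventions: risk
    differences as a one-decimal percentage with direction wording, ratios
    and E-values to two decimals, NNT to one decimal."""
    style = style or estimate.scale
    if style == "risk difference":
        if estimate.ci_low < 0 < estimate.ci_high:
            return (
                f"{100 * estimate.point:+.1f}% (95% CI: {100 * estimate.ci_low:+.1f}% "
                f"to {100 * estimate.ci_high:+.1f}%)"
            )
        direction = "lower" if estimate.point < 0 else "higher"
        lo, hi = sorted([abs(estimate.ci_low), abs(estimate.ci_high)])
        return (
            f"{100 * abs(estimate.point):.1f}% (95% CI: {100 * lo:.1f}% to "
            f"{100 * hi:.1f}%) {direction} prevalence"
        )
    if style == "risk ratio":
        return f"{estimate.point:.2f} (95% CI: {estimate.ci_low:.2f} to {estimate.ci_high:.2f})"
    if style == "mean difference":
        return (
            f"{estimate.point:.2f} mmHg (95% CI: {estimate.ci_low:.2f} to {estimate.ci_high:.2f})"
        )
    raise ValueError(f"unknown style {style!r}")


def format_nnt(nnt: float) -> str:
    return f"{nnt:.1f}"


def format_evalue(e: float) -> str:
    return f"{e:.2f}"


@dataclass
class RunBundle:
    """In-memory results of a full run (files are written separately)."""

    config: RunConfig
    master_seed: int
    cohort: pd.DataFrame
    imputed: pd.DataFrame
    effects: dict
    overlap: dict
    solution: object
    importance: object
    cluster_effects: dict
    profile: pd.DataFrame
    ite: np.ndarray
    report: str = ""
    files: dict = field(default_factory=dict)


def run_emulation(
    config: RunConfig, master_seed: int, out_dir: str | Path | None = None
) -> RunBundle:
    """Execute every stage in order and (optionally) write the artifact set:
    cohort/oracle/imputed CSVs, baseline table, effects.json, overlap.json,
    heterogeneity outputs and a human-readable report."""
    schema = default_schema()
    stage = "generate"
    try:
        gen = GENERATORS[config.generator](
            n_total=config.n_total, seed=stage_seed(master_seed, "generate")
        )
        cohort_full, oracle = generate_cohort(gen, schema)

        stage = "missingness"
        cohort_miss = impose_missingness(cohort_full, gen, schema)
        cohort = apply_eligibility(cohort_miss, *config.eligibility_days)
        oracle_df = oracle.to_frame(cohort_full["person_id"].to_numpy())
        oracle_df = oracle_df[oracle_df["person_id"].isin(cohort["person_id"])]

        base_tab = baseline_table(cohort, schema)

        stage = "impute"
        imp = rf_impute(
            cohort,
            schema,
            max_iter=config.impute_max_iter,
            trees=config.impute_trees,
            seed=stage_seed(master_seed, "impute"),
        )
        imputed = imp.completed

        stage = "ensemble"
        X = design_matrix(imputed, schema)
        ycol = OUTCOME_COLUMNS[config.outcome]
        y = imputed[ycol].to_numpy(dtype=float)
        loss = "binary" if config.outcome == "binary" else "continuous"
        model = cv_stack(
            X, y, library=config.make_library(), V=config.V,
            seed=stage_seed(master_seed, "ensemble"), loss=loss,
        )
        cf = counterfactual_predict(model, X)
        ite = compute_ite(cf)

        stage = "effects"
        effects = estimate_effects(
            X, y, n_boot=config.n_boot, seed=stage_seed(master_seed, "effects"),
            fast_boot=config.fast_boot, loss=loss, model=model,
        )

        stage = "overlap"
        overlap = propensity_overlap(
            design_matrix(imputed, schema, include_treatment=False),
            imputed[TREATMENT_COL].to_numpy(),
            seed=stage_seed(master_seed, "overlap"),
        )

        stage = "heterogeneity"
        hseed = stage_seed(master_seed, "heterogeneity")
        z = jitter_standardize(ite, noise_sd=config.noise_sd, seed=hseed)
        solution = beale_select_k(z, ward_cluster(z), alpha=config.alpha)
        importance = covariate_importance(imputed, schema, solution.labels, config.thresholds)
        c_eff = cluster_cate(ite, cf, solution.labels, n_boot=config.n_boot, seed=hseed)
        profile = cluster_profile(
            imputed, schema, solution.labels, importance,
            threshold=0.25, effects=c_eff, fallback_top=5,
        )
    except Exception as exc:
        raise RuntimeError(
            f"emulation run failed in stage {stage!r} (master seed {master_seed}): {exc}"
        ) from exc

    bundle = RunBundle(
        config=config,
        master_seed=master_seed,
        cohort=cohort,
        imputed=imputed,
        effects=effects,
        overlap=overlap,
        solution=solution,
        importance=importance,
        cluster_effects=c_eff,
        profile=profile,
        ite=ite.ite,
    )
    bundle.report = _render_report(bundle)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hte = out / "hte"
        hte.mkdir(exist_ok=True)
        s = master_seed
        _write_csv(out / "cohort.csv", cohort, s)
        (out / "schema.json").write_text(schema.to_json() + "\n")
        _write_csv(out / "oracle.csv", oracle_df, s)
        _write_csv(out / "imputed.csv", imputed, s)
        _write_csv(out / "baseline_table.csv", base_tab.drop(columns=["p_value"]).fillna(""), s)
        eff_json = {
            "config": config.to_dict(),
            "library": [spec.name for spec in model.library],
            "weights": {spec.name: float(w) for spec, w in zip(model.library, model.weights)},
            "cv_risks": {spec.name: float(r) for spec, r in zip(model.library, model.cv_risks)},
            "effects": {k: v.to_dict() for k, v in effects.items()},
        }
        if loss == "binary":
            eff_json["nnt"] = nnt_from_rd(effects["ATE"].point)
            eff_json["e_value"] = evalue_rr(effects["RR"].point)
        _write_json(out / "effects.json", eff_json, s)
        ov = {k: v for k, v in overlap.items() if k != "estimated_probabilities"}
        _write_json(out / "overlap.json", ov, s)
        _write_csv(
            hte / "labels.csv",
            pd.DataFrame({"person_id": cohort["person_id"], "cluster": solution.labels}),
            s,
        )
        _write_json(
            hte / "beale_path.json",
            {
                "k": solution.k,
                "no_significant_structure": solution.no_significant_structure,
                "path": solution.beale_path,
            },
            s,
        )
        _write_csv(hte / "importance.csv", importance.table, s)
        _write_csv(hte / "cluster_profile.csv", profile, s)
        (out / "report.md").write_text(bundle.report)
        _plot_ite_histogram(bundle.ite, out / "ite_histogram.png")
        bundle.files = {p.name: p for p in out.rglob("*") if p.is_file()}
    return bundle


def _plot_ite_histogram(ite: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(ite, bins=40, color="#4477aa", edgecolor="white")
    ax.set_xlabel("individual treatment effect (risk difference)")
    ax.set_ylabel("persons")
    ax.axvline(float(np.median(ite)), color="black", linestyle="--", linewidth=1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_report(b: RunBundle) -> str:
    binary = b.config.outcome == "binary"
    ate = b.effects["ATE"]
    lines = [
        "# Emulated-trial report (synthetic data)",
        "",
        f"Package hte-emulate v{__version__}; master seed {b.master_seed}; "
        f"n = {len(b.cohort)}; outcome = {b.config.outcome}.",
        "",
        "All numbers below are computed from a synthetic cohort and describe the",
        "pipeline, not any real population.",
        "",
        "## Average effect",
        "",
    ]
    lines.append(f"- ATE: {format_effect(ate)}")
    if binary:
        rr = b.effects["RR"]
        lines.append(f"- Risk ratio: {format_effect(rr)}")
        lines.append(f"- NNT: {format_nnt(nnt_from_rd(ate.point))}")
        lines.append(f"- E-value: {format_evalue(evalue_rr(rr.point))}")
    med = float(np.median(b.ite))
    iqr = float(np.subtract(*np.percentile(b.ite, [75, 25])) * -1)
    lines += [
        f"- ITE distribution: median {med:.2f}, IQR {abs(iqr):.2f}",
        "",
        "## Cluster structure",
        "",
        f"- Clusters chosen by Beale's test at alpha={b.config.alpha}: k = {b.solution.k}"
        + (" (no significant structure; floor of evaluated range)" if b.solution.no_significant_structure else ""),
        "",
        "| transition | F | p | significant |",
        "|---|---|---|---|",
    ]
    for e in b.solution.beale_path:
        F = e.get("F")
        p = e.get("p_value")
        lines.append(
            f"| {e['transition']} | {F if F is None else f'{F:.2f}'} | "
            f"{p if p is None else f'{p:.3g}'} | {e['significant']} |"
        )
    lines += ["", "## Covariate importance (top 10)", ""]
    top = b.importance.table.head(10)
    lines.append("| variable | importance | selected at 0.25 |")
    lines.append("|---|---|---|")
    for _, r in top.iterrows():
        lines.append(f"| {r['variable']} | {r['importance']:.3f} | {bool(r['selected_at_0.25'])} |")
    lines += ["", "## Per-cluster effects", ""]
    lines.append("| cluster | n | CATE | RR | NNT | E-value |")
    lines.append("|---|---|---|---|---|---|")
    for c, e in sorted(b.cluster_effects.items()):
        rr_s = format_effect(e.rr) if e.rr else "-"
        nnt_s = format_nnt(e.nnt) if e.nnt else "-"
        ev_s = format_evalue(e.e_value) if e.e_value else "-"
        lines.append(
            f"| {c} | {e.n} | {format_effect(e.cate)} | {rr_s} | {nnt_s} | {ev_s} |"
        )
    lines.append("")
    return "\n".join(lines)
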