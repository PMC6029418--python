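"""End-to-end pipeline: simulate/load -> fit -> assign -> coexpress -> survival -> response.

Stage outputs are tab-separated tables plus a JSON summary, each with a
provenance header (config hash, seed) so a bundle can be audited and
reproduced exactly. Figures are optional; the numeric tables are the
contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assignment as asg
from . import coexpression as coex
from . import mixture as mix
from . import response as resp
from . import survival as surv
from .cohort import (
    Cohort,
    read_clinical,
    read_expression,
    write_clinical,
    write_expression,
)
from .simulate import SurvivalModel, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be active."""

    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    index_gene: str = "NAT1"
    bin_width: float = 0.2
    max_components: int = 3
    n_starts: int = 3
    scheme: asg.SubpopulationScheme = field(default_factory=asg.default_scheme)
    alpha_global: float = 0.01
    alpha_gene: float | None = None
    survival_interval: float = 2.0
    survival_horizon: float = 10.0
    response_arm: str = "chemo_only"
    response_threshold: float = 5.0
    seed: int = 0
    output_dir: str = "mixpop_out"
    figures: bool = False

    def validate(self) -> None:
        has_files = self.expression_path is not None and self.clinical_path is not None
        if (self.synthetic is None) == (not has_files):
            raise ValueError(
                "exactly one input source required: synthetic config or "
                "expression_path + clinical_path"
            )
        if self.bin_width <= 0 or self.n_starts < 1:
            raise ValueError("invalid fitting parameters")
        if not 1 <= self.max_components <= 3:
            raise ValueError("max_components must be 1..3")
        if self.synthetic is not None:
            self.synthetic.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "survival_model" in syn and isinstance(syn["survival_model"], dict):
                syn["survival_model"] = SurvivalModel(**syn["survival_model"])
            for key in ("component_weights", "component_means", "component_sds"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "scheme" in kwargs and isinstance(kwargs["scheme"], dict):
            kwargs["scheme"] = asg.SubpopulationScheme(
                low=asg.Window(*kwargs["scheme"]["low"]),
                intermediate=asg.Window(*kwargs["scheme"]["intermediate"]),
                high=asg.Window(*kwargs["scheme"]["high"]),
            )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific parameters (not output location/figures)."""
        payload = _to_jsonable(self)
        payload.pop("output_dir", None)
        payload.pop("figures", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dictionary.

    Any stage failure aborts with the stage name attached; outputs of the
    stages already finished are left on disk.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "input"
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            write_expression(cohort.expression, outdir / "expression.tsv")
            write_clinical(cohort.clinical, outdir / "clinical.tsv")
        else:
            cohort = Cohort(
                expression=read_expression(config.expression_path),
                clinical=read_clinical(config.clinical_path),
                index_gene=config.index_gene,
            )
        values = cohort.index_values()
        summary["n_patients"] = len(cohort.clinical)
        summary["n_genes"] = cohort.expression.n_genes

        stage = "fit"
        freq = mix.bin_values(values, bin_width=config.bin_width)
        fit = mix.select_model(
            freq, max_components=config.max_components,
            n_starts=config.n_starts, seed=config.seed,
        )
        norm_res = mix.ks_normality(values, seed=config.seed)
        _write_tsv(
            pd.DataFrame(
                {
                    "bin_center": freq.centers,
                    "observed": freq.counts,
                    "predicted": fit.predicted_counts,
                }
            ),
            outdir / "fit_bins.tsv",
            prov + [f"stage=fit n_components={fit.n_components}"],
        )
        summary["fit"] = {
            "n_components": fit.n_components,
            "components": [
                {"amplitude": c.amplitude, "mean": c.mean, "sd": c.sd}
                for c in fit.components
            ],
            "aucs": fit.aucs.tolist(),
            "weights_pct": (100 * fit.weights).round(1).tolist(),
            "pearson_r_obs_pred": fit.pearson_r_obs_pred,
            "syx": fit.syx,
            "converged": fit.converged,
            "ks_distance": norm_res.ks_distance,
            "ks_p": norm_res.p_value,
        }

        stage = "assign"
        labels = asg.assign(values, config.scheme)
        mis: dict = {}
        if fit.n_components == 3 and fit.converged:
            mis = asg.misassignment(fit, config.scheme, n_total=len(values))
        else:
            logger.warning("assignment windows applied without a 3-component fit")
        label_counts = {lab: int((labels == lab).sum())
                        for lab in (*asg.LABELS, "unassigned")}
        if label_counts["unassigned"] > 0.5 * len(labels):
            logger.warning(
                "more than half of patients fall outside the windows (%d of %d)",
                label_counts["unassigned"], len(labels),
            )
        _write_tsv(
            pd.DataFrame(
                {
                    "patient_id": [r.patient_id for r in cohort.clinical],
                    "value": values,
                    "label": labels,
                }
            ),
            outdir / "assignments.tsv",
            prov + ["stage=assign"],
        )
        summary["assignment"] = {"counts": label_counts, "misassignment_pct": mis}

        stage = "coexpress"
        # screen over the expression matrix's patient order
        pos = {p: i for i, p in enumerate(cohort.expression.patient_ids)}
        matrix_labels = np.full(cohort.expression.n_patients, "unassigned", dtype=object)
        for rec, lab in zip(cohort.clinical, labels):
            matrix_labels[pos[rec.patient_id]] = lab
        screen_res = coex.screen(
            cohort, matrix_labels,
            alpha_global=config.alpha_global, alpha_gene=config.alpha_gene,
        )
        rows = [
            {
                "gene": r.gene,
                "subpopulation": r.subpopulation,
                "r": r.r,
                "p": r.p,
                "significant": int(r.significant),
            }
            for recs in screen_res.values()
            for r in recs
        ]
        _write_tsv(pd.DataFrame(rows), outdir / "coexpression.tsv", prov + ["stage=coexpress"])
        sets = coex.significant_sets(screen_res)
        venn = coex.venn_partition(
            sets.get("low", set()), sets.get("intermediate", set()), sets.get("high", set())
        )
        summary["coexpression"] = {
            "significant_counts": {k: len(v) for k, v in sets.items()},
            "venn": dataclasses.asdict(venn),
        }

        stage = "survival"
        groups, group_names = [], []
        for lab in asg.LABELS:
            recs = [r for r, l in zip(cohort.clinical, labels) if l == lab]
            if recs:
                groups.append(surv.records_to_survival(recs))
                group_names.append(lab)
        surv_summary: dict = {"groups": group_names}
        if len(groups) >= 2 and any(e.sum() > 0 for _, e in groups):
            curves = {name: surv.km_curve(*g) for name, g in zip(group_names, groups)}
            for name, curve in curves.items():
                _write_tsv(
                    pd.DataFrame(
                        {
                            "time": curve.event_times,
                            "survival": curve.survival,
                            "n_at_risk": curve.n_at_risk,
                            "n_events": curve.n_events,
                        }
                    ),
                    outdir / f"km_{name}.tsv",
                    prov + [f"stage=survival group={name}"],
                )
            lr = surv.logrank(groups, weights="mantel_cox")
            gbw = surv.logrank(groups, weights="gehan_breslow_wilcoxon")
            surv_summary["logrank_mantel_cox"] = {
                "statistic": lr.statistic, "df": lr.df, "p": lr.p,
            }
            surv_summary["gehan_breslow_wilcoxon"] = {
                "statistic": gbw.statistic, "df": gbw.df, "p": gbw.p,
            }
            if len(groups) >= 3:
                tr = surv.logrank_trend(groups)
                surv_summary["logrank_trend"] = {
                    "statistic": tr.statistic, "df": tr.df, "p": tr.p,
                }
            table = surv.at_risk_table(
                groups, interval=config.survival_interval, horizon=config.survival_horizon
            )
            ticks = np.arange(0.0, config.survival_horizon + 1e-9, config.survival_interval)
            _write_tsv(
                pd.DataFrame(table, index=group_names, columns=[f"{t:g}y" for t in ticks])
                .reset_index(names="group"),
                outdir / "at_risk.tsv",
                prov + ["stage=survival"],
            )
            surv_summary["at_risk"] = {
                name: table[i].tolist() for i, name in enumerate(group_names)
            }
        else:
            logger.warning("survival stage skipped: fewer than 2 labelled groups with events")
        summary["survival"] = surv_summary

        stage = "response"
        values_by_record = values  # index_values() is aligned to clinical order
        cls = resp.classify_patients(
            cohort.clinical, arm=config.response_arm, threshold=config.response_threshold
        )
        _write_tsv(
            pd.DataFrame(
                {"patient_id": cls.patient_ids, "status": cls.status, "reason": cls.reason}
            ),
            outdir / "response_classification.tsv",
            prov + ["stage=response"],
        )
        bins = resp.survival_bins(
            cohort.clinical, values_by_record,
            arm=config.response_arm, threshold=config.response_threshold,
        )
        bin_df = pd.DataFrame(
            {"bin": [b.label for b in bins], "n": [b.n for b in bins],
             "mean_expression": [b.mean for b in bins]}
        )
        _write_tsv(bin_df, outdir / "response_bins.tsv", prov + ["stage=response"])
        resp_summary: dict = {
            "n_resistant": int(cls.mask("resistant").sum()),
            "n_sensitive": int(cls.mask("sensitive").sum()),
            "n_excluded": int(cls.mask("excluded").sum()),
            "bins": bin_df.to_dict("records"),
            "years_per_log2": resp.years_per_log2(bins),
        }
        populated = [b for b in bins if b.n > 0]
        if len(populated) >= 2:
            anova, trend = resp.anova_trend(bins)
            resp_summary["anova"] = {"F": anova.statistic, "df": list(anova.df), "p": anova.p}
            resp_summary["trend"] = {"t": trend.statistic, "df": list(trend.df), "p": trend.p}
        classified = cls.status != "excluded"
        if cls.mask("resistant").any() and cls.mask("sensitive").any():
            curve = resp.decision_curve(
                values_by_record[classified], cls.status[classified]
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "cutoff": curve.cutoffs,
                        "sensitivity": curve.sensitivity,
                        "specificity": curve.specificity,
                    }
                ),
                outdir / "decision_curve.tsv",
                prov + ["stage=response"],
            )
            resp_summary["crossover_cutoff"] = curve.crossover_cutoff
            resp_summary["crossover_value"] = curve.crossover_value
        else:
            logger.warning("decision curve skipped: a response class is empty")
        summary["response"] = resp_summary

        if config.figures:
            stage = "figures"
            _make_figures(outdir, freq, fit, groups, group_names, summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_to_jsonable(summary), fh, indent=2, sort_keys=True)
    _write_text_summary(outdir / "summary.txt", summary, prov)
    return summary


def _write_text_summary(path: Path, summary: dict, prov: list[str]) -> None:
    lines = [f"# {p}" for p in prov]
    fit = summary.get("fit", {})
    if fit:
        lines.append("")
        lines.append("Fitted sub-populations (amplitude, mean, SD, % of patients):")
        for comp, w in zip(fit["components"], fit["weights_pct"]):
            lines.append(
                f"  A={comp['amplitude']:.1f}  mean={comp['mean']:.2f}  "
                f"sd={comp['sd']:.2f}  {w:.0f}%"
            )
        lines.append(
            f"  r(obs,pred)={fit['pearson_r_obs_pred']:.4f}  Sy.x={fit['syx']:.2f}  "
            f"K-S D={fit['ks_distance']:.4f} (p={fit['ks_p']:.3g})"
        )
    venn = summary.get("coexpression", {}).get("venn")
    if venn:
        lines.append("")
        lines.append(f"Co-expression Venn regions: {venn}")
    sv = summary.get("survival", {})
    for key in ("logrank_mantel_cox", "logrank_trend", "gehan_breslow_wilcoxon"):
        if key in sv:
            lines.append(f"{key}: chi2={sv[key]['statistic']:.3f} p={sv[key]['p']:.3g}")
    rp = summary.get("response", {})
    if "crossover_cutoff" in rp:
        lines.append(
            f"decision curve crossover: cutoff={rp['crossover_cutoff']:.2f} "
            f"sens=spec={rp['crossover_value']:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")


def _make_figures(outdir, freq, fit, groups, group_names, summary) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.bar(freq.centers, freq.counts, width=freq.bin_width * 0.9, color="0.8")
    xs = np.linspace(freq.left_edges[0], freq.left_edges[-1] + freq.bin_width, 400)
    ax.plot(xs, mix.gaussian_sum(xs, fit.components), "r-")
    ax.set_xlabel("log2 expression")
    ax.set_ylabel("patients per bin")
    fig.savefig(outdir / "fit.png", dpi=120)
    plt.close(fig)

    if groups:
        fig, ax = plt.subplots()
        for name, (t, e) in zip(group_names, groups):
            curve = surv.km_curve(t, e)
            xs = np.concatenate([[0], np.repeat(curve.event_times, 2)])
            ys = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
            ax.plot(xs, ys, label=name)
        ax.set_xlabel("years")
        ax.set_ylabel("overall survival")
        ax.legend()
        fig.savefig(outdir / "km.png", dpi=120)
        plt.close(fig)
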