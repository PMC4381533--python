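"""The two headline workflows, as functions over a RunConfig.

``pipeline_derive`` runs probeset filtering, the three two-class SAM
comparisons against the stem-cell population, the intersection that
defines the signature, and the 2.5-fold top refinement (the luminal arm
of the refinement pools both luminal populations into one group).

``pipeline_prognose`` maps a signature into a cohort's identifier space,
scores every tumour, dichotomises, fits Kaplan-Meier / log-rank / Cox,
and runs the expression-matched random-signature null.

Every written artefact carries a provenance header (package version,
config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import mascsig
from mascsig import diffexpr, io, scoring, survival
from mascsig.core import GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, seeds and paths shared by the workflows."""

    # derivation thresholds
    fdr_max: float = 0.05
    fc_min: float = 1.5
    fc_top: float = 2.5
    n_perm: int = 1000
    # prognosis settings
    scoring_method: str = "average"  # or "relevance_network"
    dichotomy: str = "top_tertile"  # or "median"
    n_lists: int = 1000
    r_threshold: float = 0.3
    alpha: float = 0.05
    n_bins: int = 10
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.fc_min < 1 or self.fc_top < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.n_perm < 1 or self.n_lists < 1:
            raise ValueError("n_perm and n_lists must be >= 1")
        if self.dichotomy not in ("top_tertile", "median"):
            raise ValueError(f"unknown dichotomy {self.dichotomy!r}")
        if self.scoring_method not in ("average", "relevance_network"):
            raise ValueError(f"unknown scoring method {self.scoring_method!r}")

    def provenance(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "mascsig_version": mascsig.__version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg


def pipeline_derive(
    matrix: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig,
    mapping: pd.DataFrame | None = None,
    stem_label: str = "MaSC",
    out_dir: str | Path | None = None,
):
    """Derive the stem-cell signature from a labelled population matrix.

    Returns a dict with the per-comparison SAM results, the signature, the
    top refinement and the combined-luminal SAM used by the refinement.
    """
    config.validate()
    if mapping is not None:
        matrix = diffexpr.filter_probesets(matrix, mapping)
        logger.info("probeset filtering: %d rows remain", matrix.shape[0])

    pops = sorted(labels.unique())
    if stem_label not in pops:
        raise ValueError(f"stem population {stem_label!r} not in labels {pops}")
    others = [p for p in pops if p != stem_label]

    comparisons: dict[str, diffexpr.SamResult] = {}
    for other in others:
        keep = labels.isin([other, stem_label])
        sub = matrix.loc[:, labels.index[keep]]
        # label order: ("0_other", stem) so positive d = up in stem cells
        grp = labels[keep].map(lambda p: "0_other" if p == other else stem_label)
        res = diffexpr.sam_two_class(sub, grp, n_perm=config.n_perm,
                                     seed=config.seed)
        comparisons[f"vs_{other}"] = res
        logger.info("SAM %s vs %s: %d genes significant",
                    stem_label, other, len(res.significant(config.fdr_max)))

    signature = diffexpr.derive_signature(
        comparisons, fdr_max=config.fdr_max, fc_min=config.fc_min
    )

    top = None
    combined = None
    if signature is not None:
        # refinement arms: vs MYO and vs the *pooled* luminal populations
        luminal = [p for p in others if p.lower().startswith("lum")]
        myo = [p for p in others if not p.lower().startswith("lum")]
        refine_inputs: dict[str, diffexpr.SamResult] = {}
        if myo:
            refine_inputs[f"vs_{myo[0]}"] = comparisons[f"vs_{myo[0]}"]
        if luminal:
            keep = labels.isin(luminal + [stem_label])
            sub = matrix.loc[:, labels.index[keep]]
            grp = labels[keep].map(
                lambda p: "0_luminal" if p in luminal else stem_label
            )
            combined = diffexpr.sam_two_class(sub, grp, n_perm=config.n_perm,
                                              seed=config.seed)
            refine_inputs["vs_luminal_combined"] = combined
        top = diffexpr.refine_top_signature(
            signature, refine_inputs, fc_min=config.fc_top, fdr_max=config.fdr_max
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = config.provenance()
        for name, res in comparisons.items():
            res.table.to_csv(out / f"sam_{name}.tsv", sep="\t")
        if signature is not None:
            io.write_signature(signature, out / "signature.txt", prov)
            gmt = {"signature": signature}
            if top is not None:
                io.write_signature(top, out / "signature_top.txt", prov)
                gmt["signature_top"] = top
            io.write_gmt(gmt, out / "signatures.gmt")

    return {
        "comparisons": comparisons,
        "signature": signature,
        "top_signature": top,
        "combined_luminal": combined,
    }


def pipeline_prognose(
    matrix: pd.DataFrame,
    survival_table: pd.DataFrame,
    signature: GeneSignature,
    config: RunConfig,
    mapping: pd.DataFrame | None = None,
    run_null: bool = True,
    out_dir: str | Path | None = None,
):
    """Score a cohort and stratify survival.

    Returns a dict with the activation scores, the group labels, the
    :class:`mascsig.survival.SurvivalFit` and (optionally) the matched
    random-signature :class:`mascsig.survival.NullDistribution`.
    """
    config.validate()
    if mapping is not None:
        signature = scoring.map_signature_ids(signature, mapping)

    if config.scoring_method == "relevance_network":
        act, network = scoring.relevance_network_score(
            matrix, signature, r_threshold=config.r_threshold, alpha=config.alpha
        )
    else:
        act = scoring.average_score(matrix, signature)
        network = None

    scores = act.scores.reindex(survival_table.index)
    if scores.isna().any():
        missing = survival_table.index[scores.isna()].tolist()
        raise ValueError(f"survival samples without expression: {missing[:5]}")
    groups = scoring.dichotomise(scores, config.dichotomy)

    table = survival_table.copy()
    table["group"] = groups
    fit = survival.cox_univariate(table)
    logger.info("log-rank chi2=%.3f p=%.3g; HR=%.3f CI=(%.3f, %.3f)",
                fit.logrank_stat, fit.logrank_p, fit.hr, *fit.ci)

    null = None
    if run_null:
        null = survival.matched_random_signature_null(
            matrix, signature, survival_table,
            n_lists=config.n_lists, scoring_method=config.scoring_method,
            dichotomy=config.dichotomy, n_bins=config.n_bins, seed=config.seed,
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = config.provenance()
        score_table = pd.DataFrame({"score": scores, "group": groups})
        score_table.index.name = "sample_id"
        with open(out / "scores.csv", "w", encoding="utf-8", newline="\n") as fh:
            for key, value in prov.items():
                fh.write(f"# {key}={value}\n")
            score_table.to_csv(fh, float_format="%.10g", lineterminator="\n")
        for label, curve in fit.km.items():
            curve.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
        summary = {
            "logrank_chi2": fit.logrank_stat,
            "logrank_p": fit.logrank_p,
            "hr": fit.hr,
            "ci_low": fit.ci[0],
            "ci_high": fit.ci[1],
            "n_retained_genes": len(act.retained_genes),
            **{f"provenance_{k}": v for k, v in prov.items()},
        }
        if null is not None:
            summary["null_p_empirical"] = null.p_empirical
            summary["null_n_lists"] = null.n_lists
        with open(out / "prognosis.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)

    return {
        "scores": act,
        "groups": groups,
        "fit": fit,
        "null": null,
        "network": network,
    }
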