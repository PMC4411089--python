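"""End-to-end analysis pipeline over a cohort TSV (or a simulated cohort).

Stages run in a fixed order — cohort summary, per-SNP population genetics
and association, HLA risk stratification, TNFA haplotype EM, combination
grouping, the joint HLA+TNFA logistic model, predictive margins, ROC
comparison and the atrophy analysis — and accumulate into one
machine-readable JSON report.  Human-readable tables are rendered from the
JSON.  Identical config and seed give byte-identical reports; wall-clock
metadata lives only in the MANIFEST.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import ttest_ind

from . import assoc, em, grouping, hla, popgen
from .cohort import SubjectRecord, read_cohort
from .loci import DEFAULT_PANEL, HAPLOTYPE_CODES, TNFA_HAPLOTYPE_LOCI, panel_subset
from .tables import ContingencyTable

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    cohort_path: Optional[str] = None
    covariates: Tuple[str, ...] = assoc.COVARIATE_PROFILE
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 3
    bands: Tuple[float, ...] = grouping.DEFAULT_BANDS
    prevalence: float = 184.0
    rounding: str = "paper"
    multiplicity: int = 10
    seed: int = 0
    skip_tnfa: bool = False
    assignment_policy: str = "map"
    atrophy_grades: Tuple[str, ...] = ("3c",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline settings: {sorted(unknown)}")
        for key in ("covariates", "bands", "atrophy_grades"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _opt(res: assoc.AssociationResult) -> dict:
    return {
        "term": res.term,
        "or": res.or_est,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p": res.p,
        "p_adj": res.p_adj,
        "model": res.model,
        "n_used": res.n_used,
    }


def _stage_cohort_summary(subjects: Sequence[SubjectRecord]) -> dict:
    cases = [s for s in subjects if s.is_case]
    controls = [s for s in subjects if not s.is_case]
    out: dict = {"n_cases": len(cases), "n_controls": len(controls)}

    sex_tab = ContingencyTable(
        ("case", "control"),
        ("F", "M"),
        [
            [sum(s.sex == "F" for s in grp), sum(s.sex == "M" for s in grp)]
            for grp in (cases, controls)
        ],
    )
    stat, df, p = assoc.chi_square(sex_tab)
    out["sex"] = {"counts": sex_tab.counts.tolist(), "chi2": stat, "p": p}

    age_case = [s.age for s in cases if s.age is not None]
    age_ctrl = [s.age for s in controls if s.age is not None]
    if age_case and age_ctrl:
        t, p = ttest_ind(age_ctrl, age_case, equal_var=True)
        out["age"] = {
            "case_mean": float(np.mean(age_case)),
            "case_sd": float(np.std(age_case, ddof=1)),
            "control_mean": float(np.mean(age_ctrl)),
            "control_sd": float(np.std(age_ctrl, ddof=1)),
            "t": float(t),
            "p": float(p),
        }

    hp = [
        [sum(s.hpylori == "yes" for s in grp), sum(s.hpylori == "no" for s in grp)]
        for grp in (cases, controls)
    ]
    if all(sum(row) > 0 for row in hp):
        tab = ContingencyTable(("case", "control"), ("yes", "no"), hp)
        stat, df, p = assoc.chi_square(tab)
        out["hpylori"] = {"counts": hp, "chi2": stat, "p": p}

    out["marsh"] = {
        level: sum(s.marsh == level for s in cases) for level in ("1", "2", "3a", "3b", "3c")
    }
    return out


def _stage_popgen(subjects: Sequence[SubjectRecord]) -> dict:
    out: dict = {}
    for locus in DEFAULT_PANEL:
        counts = popgen.genotype_counts(subjects, locus)
        if sum(counts) == 0:
            continue
        entry: dict = {
            "counts_minor_het_major": list(counts),
            "maf": popgen.allele_freq(counts),
        }
        hwe = popgen.hwe_exact(counts, locus.locus_id)
        entry["hwe_p_exact"] = hwe.p_exact
        entry["hwe_chi2"] = hwe.chi2
        out[locus.locus_id] = entry
    return out


def _stage_snp_association(
    subjects: Sequence[SubjectRecord], covariates: Sequence[str]
) -> dict:
    out: dict = {}
    for locus in DEFAULT_PANEL:
        entry: dict = {}
        for model in ("dominant", "recessive"):
            for label, covs in (("crude", ()), ("adjusted", tuple(covariates))):
                key = f"{model}_{label}"
                try:
                    entry[key] = _opt(assoc.snp_association(subjects, locus, model, covs))
                except (ValueError, assoc.SeparationError) as exc:
                    entry[key] = {"error": str(exc)}
        out[locus.locus_id] = entry
    return out


def _stage_hla(
    subjects: Sequence[SubjectRecord], prevalence: float, rounding: str
) -> Tuple[dict, List[hla.HLACategory]]:
    categories = [
        hla.classify_hla(s.dqa1_alleles, s.dqb1_alleles) for s in subjects
    ]
    out: dict = {"categories": {}}
    neg_cases = sum(
        1 for s, c in zip(subjects, categories) if c is hla.HLACategory.NEG and s.is_case
    )
    neg_ctrl = sum(
        1
        for s, c in zip(subjects, categories)
        if c is hla.HLACategory.NEG and not s.is_case
    )
    for cat in hla.HLACategory:
        n_case = sum(
            1 for s, c in zip(subjects, categories) if c is cat and s.is_case
        )
        n_ctrl = sum(
            1 for s, c in zip(subjects, categories) if c is cat and not s.is_case
        )
        if n_case + n_ctrl == 0:
            continue
        entry: dict = {
            "cases": n_case,
            "controls": n_ctrl,
            "tier": hla.risk_tier(cat).value,
        }
        if n_case > 0:
            risk = hla.posttest_risk(n_case, n_ctrl, prevalence, rounding, cat)
            risk_exact = hla.posttest_risk(n_case, n_ctrl, prevalence, "exact", cat)
            entry["risk_1_in_N"] = risk.N
            entry["risk_1_in_N_exact"] = risk_exact.N
        if cat is not hla.HLACategory.NEG and min(neg_cases, neg_ctrl) >= 0:
            tab = ContingencyTable(
                ("exposed", "reference"),
                ("case", "control"),
                [[n_case, n_ctrl], [neg_cases, neg_ctrl]],
            )
            try:
                entry["or_vs_neg"] = _opt(assoc.crude_or(tab))
            except ValueError as exc:
                entry["or_vs_neg"] = {"error": str(exc)}
        out["categories"][cat.value] = entry
    return out, categories


def _stage_haplotypes(
    subjects: Sequence[SubjectRecord], config: PipelineConfig
) -> Tuple[dict, em.HaplotypeFreqTable, List[Optional[Tuple[str, str]]]]:
    panel = panel_subset(DEFAULT_PANEL, TNFA_HAPLOTYPE_LOCI)
    pooled = em.em_haplotype_freqs(
        subjects,
        panel,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        n_restarts=config.em_restarts,
        seed=config.seed,
    )
    out: dict = {
        "panel": list(pooled.panel),
        "pooled": {
            "freqs": pooled.report(),
            "loglik": pooled.loglik,
            "n_used": pooled.n_used,
            "converged": pooled.converged,
        },
        "codes": {h: HAPLOTYPE_CODES.get(h, h) for h in pooled.report()},
    }
    for label, status in (("cases", "case"), ("controls", "control")):
        grp = [s for s in subjects if s.status == status]
        if not grp:
            continue
        tab = em.em_haplotype_freqs(
            grp, panel, tol=config.em_tol, max_iter=config.em_max_iter,
            n_restarts=config.em_restarts, seed=config.seed,
        )
        out[label] = {"freqs": tab.report(), "n_used": tab.n_used}

    try:
        hap_ors = assoc.haplotype_or(
            subjects, pooled, panel, covariates=config.covariates
        )
        out["haplotype_or"] = [_opt(r) for r in hap_ors]
    except (ValueError, assoc.SeparationError) as exc:
        out["haplotype_or"] = {"error": str(exc)}

    assignments: List[Optional[Tuple[str, str]]] = []
    for s in subjects:
        try:
            post = em.diplotype_posteriors(s, pooled, panel)
        except ValueError:
            assignments.append(None)
            continue
        assignments.append(em.assign_diplotype(post, policy=config.assignment_policy))
    return out, pooled, assignments


def run_pipeline(
    config: PipelineConfig,
    subjects: Optional[Sequence[SubjectRecord]] = None,
    out_dir: Optional[str] = None,
) -> dict:
    """Run the full analysis; returns (and optionally writes) the report."""
    if subjects is None:
        if config.cohort_path is None:
            raise ValueError("either subjects or config.cohort_path is required")
        subjects = read_cohort(config.cohort_path, DEFAULT_PANEL)

    report: dict = {
        "settings": {
            "covariates": list(config.covariates),
            "bands": list(config.bands),
            "prevalence": config.prevalence,
            "rounding": config.rounding,
            "multiplicity": config.multiplicity,
            "seed": config.seed,
            "assignment_policy": config.assignment_policy,
            "atrophy_grades": list(config.atrophy_grades),
        }
    }
    manifest: dict = {"stages": {}}

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write(out_dir, report, manifest)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return result

    report["cohort_summary"] = run_stage(
        "cohort_summary", lambda: _stage_cohort_summary(subjects)
    )
    report["popgen"] = run_stage("popgen", lambda: _stage_popgen(subjects))
    report["snp_association"] = run_stage(
        "snp_association", lambda: _stage_snp_association(subjects, config.covariates)
    )
    hla_report, categories = run_stage(
        "hla_risk", lambda: _stage_hla(subjects, config.prevalence, config.rounding)
    )
    report["hla_risk"] = hla_report
    tiers = [hla.risk_tier(c) for c in categories]

    if not config.skip_tnfa:
        hap_report, freq_table, assignments = run_stage(
            "haplotypes", lambda: _stage_haplotypes(subjects, config)
        )
        report["haplotypes"] = hap_report

        def _combos():
            triplets = [
                (s.subject_id, s.status, pair)
                for s, pair in zip(subjects, assignments)
            ]
            table = grouping.combo_table(triplets, bands=config.bands)
            return table, {
                "table": table.df.to_dict(orient="records"),
                "n_unassigned": table.n_unassigned,
            }

        combo_tbl, combo_json = run_stage("combinations", _combos)
        report["combinations"] = combo_json

        group_map = combo_tbl.as_map()
        groups = [
            group_map[grouping.combo_key(pair)] if pair is not None else None
            for pair in assignments
        ]
        usable = [i for i, g in enumerate(groups) if g is not None]

        def _joint():
            # a reference cell with one status only (e.g. no HLA-negative
            # cases drawn) makes the MLE infinite; report the degeneracy
            # instead of aborting the run
            try:
                fit, results = grouping.joint_model(
                    [subjects[i] for i in usable],
                    [tiers[i] for i in usable],
                    [groups[i] for i in usable],
                    covariates=config.covariates,
                    multiplicity=config.multiplicity,
                )
            except (assoc.SeparationError, ValueError, np.linalg.LinAlgError) as exc:
                return None, {"error": str(exc)}
            return fit, {
                "terms": list(fit.terms),
                "coef": fit.coef.tolist(),
                "se": fit.se.tolist(),
                "loglik": fit.loglik,
                "n_used": fit.n_used,
                "converged": fit.converged,
                "odds_ratios": [_opt(r) for r in results],
            }

        joint_fit, joint_json = run_stage("joint_model", _joint)
        report["joint_model"] = joint_json

        def _margins():
            if joint_fit is None:
                return {"error": "joint model not estimable"}
            return [
                dataclasses.asdict(m)
                for m in grouping.marginal_probabilities(
                    joint_fit,
                    [subjects[i] for i in usable],
                    [tiers[i] for i in usable],
                    [groups[i] for i in usable],
                    covariates=config.covariates,
                )
            ]

        report["margins"] = run_stage("margins", _margins)

        def _roc():
            try:
                return _roc_inner()
            except (assoc.SeparationError, ValueError, np.linalg.LinAlgError) as exc:
                return {"error": str(exc)}

        def _roc_inner():
            cov_mat, cov_names, mask = assoc.covariate_design(
                [subjects[i] for i in usable], config.covariates
            )
            idx = np.flatnonzero(mask)
            y = np.array(
                [1.0 if subjects[usable[i]].is_case else 0.0 for i in idx]
            )
            tier_arr = np.array([tiers[usable[i]].name for i in idx])
            tier_cols = np.column_stack(
                [(tier_arr == lv).astype(float) for lv in ("INTERMEDIATE", "HIGH")]
            )
            X_hla = np.column_stack([np.ones(len(idx)), tier_cols, cov_mat[idx]])
            hla_fit = assoc.fit_logistic(
                y, X_hla, terms=["intercept", "tier_INTERMEDIATE", "tier_HIGH"] + cov_names
            )
            group_arr = np.array([groups[usable[i]] for i in idx])
            extra, extra_names = [], []
            for lv in grouping.GROUP_LABELS[1:]:
                col = (group_arr == lv).astype(float)
                if col.any():
                    extra.append(col)
                    extra_names.append(f"group_{lv}")
            X_full = np.column_stack([X_hla] + [np.column_stack(extra)])
            full_fit = assoc.fit_logistic(
                y,
                X_full,
                terms=["intercept", "tier_INTERMEDIATE", "tier_HIGH"]
                + cov_names
                + extra_names,
            )
            auc_a, auc_b, p = assoc.roc_compare(hla_fit, full_fit)
            return {"auc_hla": auc_a, "auc_hla_tnfa": auc_b, "p_delong": p}

        report["roc"] = run_stage("roc", _roc)

        def _atrophy():
            out: dict = {}
            cd_idx = [i for i in usable if subjects[i].is_case]
            atrophy = [
                s
                for i, s in ((i, subjects[i]) for i in cd_idx)
                if s.marsh is not None
            ]
            if atrophy:
                homo: List[SubjectRecord] = []
                rest: List[SubjectRecord] = []
                for s in atrophy:
                    tier_name = hla.risk_tier(
                        hla.classify_hla(s.dqa1_alleles, s.dqb1_alleles)
                    ).name
                    (homo if tier_name == "HIGH" else rest).append(s)
                def n_atr(grp):
                    return sum(s.marsh in config.atrophy_grades for s in grp)
                if homo and rest:
                    tab = ContingencyTable(
                        ("DQ25_HOMO", "OTHER_CD"),
                        ("atrophy", "no_atrophy"),
                        [
                            [n_atr(homo), len(homo) - n_atr(homo)],
                            [n_atr(rest), len(rest) - n_atr(rest)],
                        ],
                    )
                    out["atrophy_by_hla"] = {
                        "counts": tab.counts.tolist(),
                        "or": _opt(assoc.crude_or(tab)),
                    }
            for stratum, tier_name in (("intermediate", "INTERMEDIATE"), ("high", "HIGH")):
                strat_idx = [
                    i for i in cd_idx
                    if tiers[i].name == tier_name and subjects[i].marsh is not None
                ]
                if not strat_idx:
                    continue
                try:
                    res = grouping.atrophy_trend(
                        [subjects[i] for i in strat_idx],
                        [groups[i] for i in strat_idx],
                        atrophy_grades=config.atrophy_grades,
                    )
                    out[f"trend_{stratum}"] = _opt(res)
                except (ValueError, np.linalg.LinAlgError, assoc.SeparationError) as exc:
                    out[f"trend_{stratum}"] = {"error": str(exc)}
            return out

        report["atrophy"] = run_stage("atrophy", _atrophy)

    manifest["completed"] = True
    _write(out_dir, report, manifest)
    return report


def _render_tables(report: dict, out_path: Path) -> None:
    lines: List[str] = []
    hap = report.get("haplotypes")
    if hap:
        lines.append("haplotype\tcode\tpooled_freq")
        for h, f in sorted(hap["pooled"]["freqs"].items()):
            lines.append(f"{h}\t{hap['codes'].get(h, h)}\t{f:.4f}")
        lines.append("")
    combos = report.get("combinations")
    if combos and isinstance(combos.get("table"), list):
        lines.append("combination\tn_cd\tn_ctrl\tcd_fraction\tgroup")
        for row in combos["table"]:
            lines.append(
                f"{row['combination']}\t{row['n_cd']}\t{row['n_ctrl']}"
                f"\t{row['cd_fraction']:.4f}\t{row['group']}"
            )
        lines.append("")
    out_path.write_text("\n".join(lines), encoding="utf-8")


def _write(out_dir: Optional[str], report: dict, manifest: dict) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    _render_tables(report, out / "tables.tsv")
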