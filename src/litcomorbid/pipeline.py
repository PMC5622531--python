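"""End-to-end orchestration: rank -> map -> cohort -> phenotype -> stats.

Every stage persists its artifact into the output directory so any stage
can be audited or re-run from its inputs: panel CSV, mapping echo, calls
CSV, matches JSONL, prevalence CSV, attribution CSV and a summary JSON,
plus a run log with row counts per stage and a config hash.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import EhrBundle, select_cohort
from .errors import LitComorbidError
from .fixtures import load_default_mappings, load_index_mapping
from .literature import parse_cooccurrence, parse_descriptors, rank_comorbidities, subtree_members
from .phenotype import (
    adjudicate,
    attribute_sources,
    attributions_to_frame,
    calls_to_frame,
    combine_sources,
    detect_drug_cases,
    detect_icd_cases,
    scan_documents,
    text_cases_from_adjudication,
    text_cases_from_matches,
)
from .stats import burden_summary, prevalence_ci, sperrin_I, spearman_rho
from .terminology import parse_mapping_config

log = logging.getLogger("litcomorbid")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    bundle_dir: str
    out_dir: str
    descriptors_path: str | None = None
    cooccurrence_path: str | None = None
    mapping_path: str | None = None  # defaults to the shipped mapping
    votes_path: str | None = None
    index_dui: str = "D002446"
    subtree_root: str = "C20.111"
    top_k: int = 15
    window: tuple[str, str] = ("2000-01-01", "2014-12-31")
    dept_filter: str = "gastroenterology"
    policy: str = "consensus"
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "window" in doc:
            doc["window"] = tuple(doc["window"])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()


def _stage(name: str, counts: dict, **info) -> None:
    log.info("stage %s: %s", name, info)
    counts[name] = info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the workflow; returns the summary dict written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stage = "setup"
    try:
        # --- literature ranking (optional: needs descriptor + cooc files)
        stage = "rank"
        panel_duis: list[str]
        if config.descriptors_path and config.cooccurrence_path:
            descriptors = parse_descriptors(Path(config.descriptors_path).read_text(encoding="utf-8"))
            records = parse_cooccurrence(Path(config.cooccurrence_path).read_text(encoding="utf-8"))
            allowed = subtree_members(descriptors, config.subtree_root)
            allowed.discard(config.index_dui)
            panel = rank_comorbidities(
                records, config.index_dui, allowed, config.top_k, config.subtree_root
            )
            panel.to_frame().to_csv(out / "panel.csv", index=False)
            panel_duis = list(panel.duis)
            panel_counts = dict(panel.members)
            _stage("rank", counts, records=len(records), panel=len(panel_duis))
        else:
            from .fixtures import fixture_tables

            tbl = fixture_tables()["panel"]
            tbl[["dui", "n_cooccurrence"]].to_csv(out / "panel.csv", index=False)
            panel_duis = list(tbl["dui"])
            panel_counts = dict(zip(tbl["dui"], tbl["n_cooccurrence"]))
            _stage("rank", counts, records=0, panel=len(panel_duis), source="shipped panel")

        # --- terminology
        stage = "mapping"
        if config.mapping_path:
            mappings = parse_mapping_config(Path(config.mapping_path).read_text(encoding="utf-8"))
        else:
            mappings = load_default_mappings()
        mappings = {d: m for d, m in mappings.items() if d in set(panel_duis)}
        from .terminology import serialize_mapping_config

        (out / "mapping_echo.yaml").write_text(serialize_mapping_config(mappings), encoding="utf-8")
        _stage("mapping", counts, diseases=len(mappings))

        # --- cohort
        stage = "cohort"
        bundle = EhrBundle.from_dir(config.bundle_dir)
        index_map = load_index_mapping()
        cohort = select_cohort(
            bundle, index_map.icd[0], index_map.terms, config.dept_filter, config.window
        )
        pd.Series(sorted(cohort), name="patient_id").to_csv(out / "cohort.csv", index=False)
        _stage("cohort", counts, patients=len(bundle.patients), included=len(cohort))

        # --- phenotyping
        stage = "phenotype"
        icd_cases = detect_icd_cases(bundle, mappings, cohort)
        drug_cases = detect_drug_cases(bundle, mappings, cohort)
        matches = scan_documents(bundle, mappings, cohort)
        with open(out / "matches.jsonl", "w", encoding="utf-8") as fh:
            for m in matches:
                fh.write(json.dumps(dataclasses.asdict(m)) + "\n")
        unresolved = 0
        if config.votes_path:
            votes = pd.read_csv(config.votes_path, dtype=str)
            items = adjudicate(matches, votes, config.policy)
            text_cases = text_cases_from_adjudication(items)
            unresolved = sum(1 for i in items if i.resolution == "unresolved")
        else:
            text_cases = text_cases_from_matches(matches)
        calls = combine_sources(icd_cases, drug_cases, text_cases, cohort, panel_duis)
        calls_to_frame(calls).to_csv(out / "calls.csv", index=False)
        _stage(
            "phenotype",
            counts,
            icd=len(icd_cases),
            drug=len(drug_cases),
            text=len(text_cases),
            matches=len(matches),
            unresolved=unresolved,
        )

        # --- statistics
        stage = "stats"
        n_total = len(cohort)
        prev_rows = []
        case_count = {d: 0 for d in panel_duis}
        for c in calls:
            if c.present:
                case_count[c.dui] += 1
        for dui in panel_duis:
            est = prevalence_ci(case_count[dui], n_total, alpha=config.alpha, dui=dui)
            p, lo, hi = est.rounded()
            prev_rows.append(
                {
                    "dui": dui,
                    "n_cases": est.n_cases,
                    "per_1000": p,
                    "ci_low": lo,
                    "ci_high": hi,
                    "method": est.method,
                }
            )
        prev_df = pd.DataFrame(prev_rows)
        prev_df.to_csv(out / "prevalence.csv", index=False)

        attribs = attribute_sources(calls)
        attributions_to_frame(attribs).to_csv(out / "attribution.csv", index=False)

        burden = burden_summary(calls, alpha=config.alpha)

        # regularity over patients with >= 2 distinct encounter dates
        enc = bundle.encounters[bundle.encounters["patient_id"].isin(cohort)]
        scores = []
        for pid, grp in enc.groupby("patient_id"):
            dates = sorted(set(pd.to_datetime(grp["date"]).dt.date))
            if len(dates) >= 2:
                scores.append(sperrin_I(dates, patient_id=pid).I)
        mean_I = float(pd.Series(scores).mean()) if scores else None

        rho = None
        if len(panel_duis) >= 3:
            x = [panel_counts[d] for d in panel_duis]
            y = [case_count[d] for d in panel_duis]
            try:
                rho = spearman_rho(x, y).rho
            except LitComorbidError:
                rho = None

        summary = {
            "n_cohort": n_total,
            "burden_per_1000": burden.p_per_1000,
            "burden_ci_per_1000": [burden.ci_low_per_1000, burden.ci_high_per_1000],
            "burden_method": burden.method,
            "spearman_rho_vs_literature": rho,
            "mean_sperrin_I": mean_I,
            "n_regularity_patients": len(scores),
            "unresolved_items": unresolved,
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _stage("stats", counts, diseases=len(prev_rows))

        run_log = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "stages": counts,
            "finished_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        }
        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(run_log, fh, indent=2, default=str)
        return summary
    except Exception as exc:
        raise LitComorbidError(f"pipeline failed at stage {stage!r}: {exc}") from exc
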