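"""In-package reference data: the published panel, prevalence table, vote
partition and the default detector mappings for the celiac-disease /
autoimmune-comorbidity study.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .stats import AgreementTable
from .terminology import DiseaseMapping, parse_mapping_config

__all__ = [
    "COHORT_SIZE",
    "VOTE_PARTITION",
    "fixture_tables",
    "load_default_mappings",
    "load_index_mapping",
]

#: Size of the published study cohort.
COHORT_SIZE = 741

#: Two-reviewer vote partition over the 466 reviewed text items:
#: both approve / both reject / disagreements (split between the two
#: disagreement directions is not published; 22 is their total).
VOTE_PARTITION = {"both_approve": 140, "both_reject": 304, "disagree": 22}


def _data_text(name: str) -> str:
    return resources.files("litcomorbid.data").joinpath(name).read_text(encoding="utf-8")


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Published reference tables as DataFrames.

    Keys:

    * ``panel`` — the 15 autoimmune comorbidities of celiac disease, with
      MEDLINE co-occurrence counts and ICD-10 patterns;
    * ``prevalence`` — observed case counts (of 741 patients) and the
      printed per-1000 estimates with their CIs;
    * ``literature`` — prevalence ranges from prior studies, shipped as a
      static reference only.
    """
    import io

    return {
        "panel": pd.read_csv(io.StringIO(_data_text("panel_celiac_autoimmune.csv"))),
        "prevalence": pd.read_csv(io.StringIO(_data_text("prevalence_celiac_autoimmune.csv"))),
        "literature": pd.read_csv(io.StringIO(_data_text("literature_prevalence_reference.csv"))),
    }


def agreement_table(n_disagree_ab: int = 11) -> AgreementTable:
    """The published vote partition as a 2x2 table.

    Only the total of 22 disagreements is published; *n_disagree_ab*
    chooses the split (kappa is insensitive to it at 2 decimals).
    """
    d = VOTE_PARTITION["disagree"]
    if not 0 <= n_disagree_ab <= d:
        raise ValueError(f"split must lie in [0, {d}]")
    return AgreementTable(
        n_both_approve=VOTE_PARTITION["both_approve"],
        n_both_reject=VOTE_PARTITION["both_reject"],
        n_disagree_ab=n_disagree_ab,
        n_disagree_ba=d - n_disagree_ab,
    )


def load_default_mappings() -> dict[str, DiseaseMapping]:
    """The 15 panel-disease detector mappings shipped with the package."""
    return parse_mapping_config(_data_text("mappings_celiac_autoimmune.yaml"))


def load_index_mapping() -> DiseaseMapping:
    """The index-disease (celiac) mapping used for cohort selection."""
    doc = yaml.safe_load(_data_text("mappings_celiac_autoimmune.yaml"))
    wrapped = yaml.safe_dump({"diseases": [doc["index"]]}, allow_unicode=True)
    return next(iter(parse_mapping_config(wrapped).values()))
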