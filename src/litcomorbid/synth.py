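"""Synthetic study inputs with known ground truth.

Two generators make every pipeline stage testable without access to real
clinical data:

* :func:`generate_cooccurrence` — a descriptor table and a co-occurrence
  file with a planted, descending count sequence for the panel diseases and
  decoy pairs outside the target subtree (including decoys whose counts
  exceed the planted ones, so subtree restriction is actually exercised);
* :func:`generate_bundle` — an EHR bundle where each patient's case status
  per disease is Bernoulli with a configured prevalence, and each of the
  three sources fires conditionally on case status with its own
  sensitivity: a text firing inserts a disease mention into a generated
  document (French or English template, exercising accent folding), an ICD
  firing adds a matching billing code, a drug firing adds a matching
  prescription.

Defaults emulate the published study's conditions: a 741-patient cohort,
per-disease prevalences equal to the published case counts over 741, and
source sensitivities dominated by text (text is involved in ~95% of
detections in the published source-attribution split).  By default
non-cases never fire a detector; a false-positive knob exists for
robustness tests, and a correlation knob (shared latent severity) lets the
three sources co-fire more often than independence predicts.

Everything is driven by one seeded generator: identical configs give
byte-identical bundles.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import EhrBundle
from .fixtures import fixture_tables, COHORT_SIZE
from .literature import MeshDescriptor, CooccurrenceRecord

__all__ = [
    "SynthDisease",
    "SynthConfig",
    "default_config",
    "generate_bundle",
    "generate_cooccurrence",
    "bundle_hash",
    "fixture_tables",
]

# (french mention, english mention) per panel disease; each mention matches
# the corresponding TermPattern of the shipped mapping after accent folding.
_MENTIONS: dict[str, tuple[str, str]] = {
    "D003922": ("diabète de type 1", "type 1 diabetes mellitus"),
    "D003874": ("dermatite herpétiforme", "dermatitis herpetiformis"),
    "D013967": ("thyroïdite de Hashimoto", "autoimmune thyroiditis"),
    "D001172": ("polyarthrite rhumatoïde", "rheumatoid arthritis"),
    "D008180": ("lupus érythémateux disséminé", "systemic lupus"),
    "D009103": ("sclérose en plaques", "multiple sclerosis"),
    "D012859": ("syndrome de Gougerot-Sjögren", "Sjogren syndrome"),
    "D000224": ("maladie d'Addison", "Addison disease"),
    "D001171": ("arthrite juvénile", "juvenile idiopathic arthritis"),
    "D019693": ("hépatite auto-immune", "autoimmune hepatitis"),
    "D006111": ("maladie de Basedow", "Graves disease"),
    "D005922": ("maladie de Berger", "IgA nephropathy"),
    "D009157": ("myasthénie", "myasthenia gravis"),
    "D016884": ("polyendocrinopathie auto-immune", "autoimmune polyendocrinopathy"),
    "D016736": ("syndrome des antiphospholipides", "antiphospholipid syndrome"),
}

# Concrete codes the generator emits; each falls under the shipped mapping's
# ICD pattern / ATC prefix for its disease.
_ICD_CODES: dict[str, str] = {
    "D003922": "E101", "D003874": "L130", "D013967": "E063", "D001172": "M069",
    "D008180": "M320", "D009103": "G35", "D012859": "M350", "D000224": "E271",
    "D001171": "M089", "D019693": "K754", "D006111": "E050", "D005922": "N0330",
    "D009157": "G700", "D016884": "E310", "D016736": "D686",
}
_ATC_CODES: dict[str, str] = {"D003922": "A10AB01", "D013967": "H03AA01"}

_TEMPLATES = {
    "fr": (
        "Patient suivi pour maladie cœliaque au régime sans gluten. "
        "Compte rendu de consultation de gastro-entérologie."
    ),
    "en": (
        "Patient followed for celiac disease on a gluten-free diet. "
        "Gastroenterology outpatient report."
    ),
}
_MENTION_TEMPLATES = {
    "fr": "Antécédents notables : {mention}, suivie dans notre service.",
    "en": "Relevant history: {mention}, followed in our department.",
}

_DEPARTMENTS = ["gastroenterology", "endocrinology", "internal medicine", "dermatology"]


@dataclass(frozen=True)
class SynthDisease:
    """Ground-truth parameters for one panel disease."""

    dui: str
    name: str
    true_prevalence: float
    p_text: float = 0.95
    p_icd: float = 0.15
    p_drug: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.true_prevalence, self.p_text, self.p_icd, self.p_drug):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability out of [0,1] for {self.dui}: {v}")


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int
    seed: int
    diseases: tuple[SynthDisease, ...]
    # shifted negative binomial: n_encounters = 1 + NB(r, p); defaults give
    # a median of ~3 encounters per patient
    encounters_nb: tuple[float, float] = (2.0, 0.5)
    regularity: str = "jittered"  # "regular" | "jittered" | "clustered"
    jitter: float = 0.3  # gap-relative noise scale for "jittered"
    window: tuple[str, str] = ("2000-01-01", "2014-12-31")
    registry_fraction: float = 0.6
    french_fraction: float = 0.7
    source_correlation: float = 0.0  # shared latent severity across sources
    false_positive_rate: float = 0.0  # per-source firing rate for non-cases
    decoy_pairs: int = 40

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.regularity not in {"regular", "jittered", "clustered"}:
            raise ValueError(f"unknown regularity spec {self.regularity!r}")


def default_config(seed: int, n_patients: int = COHORT_SIZE, **overrides) -> SynthConfig:
    """Study-condition defaults: published case counts over 741 as prevalences."""
    tables = fixture_tables()
    prev = dict(zip(tables["prevalence"]["dui"], tables["prevalence"]["n_cases"]))
    diseases = tuple(
        SynthDisease(
            dui=row.dui,
            name=row.name,
            true_prevalence=prev.get(row.dui, 0) / COHORT_SIZE,
        )
        for row in tables["panel"].itertuples(index=False)
    )
    return SynthConfig(n_patients=n_patients, seed=seed, diseases=diseases, **overrides)


def _encounter_positions(rng: np.random.Generator, n: int, mode: str, jitter: float) -> np.ndarray:
    """Positions in [0, 1] for n >= 2 encounters, endpoints pinned."""
    if n == 1:
        return np.array([0.0])
    base = np.linspace(0.0, 1.0, n)
    if mode == "regular":
        return base
    if mode == "jittered":
        noise = rng.normal(0.0, jitter / max(n - 1, 1), size=n)
        pos = np.sort(np.clip(base + noise, 0.0, 1.0))
    else:  # clustered: irregular visit pattern
        pos = np.sort(rng.uniform(0.0, 1.0, size=n))
    pos[0], pos[-1] = 0.0, 1.0
    return pos


def _fire_sources(
    rng: np.random.Generator, n: int, probs: tuple[float, float, float], rho: float
) -> np.ndarray:
    """(n, 3) boolean firing matrix, optionally correlated via a latent."""
    if rho == 0.0:
        return rng.random((n, 3)) < np.asarray(probs)
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, 3))
    latent = norm.cdf(np.sqrt(rho) * z + np.sqrt(1 - rho) * eps)
    return latent < np.asarray(probs)


def generate_bundle(config: SynthConfig) -> tuple[EhrBundle, pd.DataFrame]:
    """Generate an EHR bundle plus the ground-truth case table.

    Returns ``(bundle, truth)`` where *truth* has one row per
    (patient, disease) with the planted boolean ``case`` status.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:05d}" for i in range(1, n + 1)]

    sex = np.where(rng.random(n) < 0.736, "female", "male")
    age = np.clip(rng.normal(42.5, 16.9, n), 18.0, 95.0).round(1)
    registry = rng.random(n) < config.registry_fraction
    french = rng.random(n) < config.french_fraction

    start = dt.date.fromisoformat(config.window[0])
    end = dt.date.fromisoformat(config.window[1])
    window_days = (end - start).days

    r_nb, p_nb = config.encounters_nb
    n_enc = 1 + rng.negative_binomial(r_nb, p_nb, size=n)

    enc_rows: list[tuple] = []
    doc_rows: list[tuple] = []
    diag_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    first_dates: list[dt.date] = []

    for i, pid in enumerate(pids):
        k = int(n_enc[i])
        t0 = int(rng.integers(0, max(window_days - 365, 1)))
        span = int(rng.integers(0, window_days - t0)) if k > 1 else 0
        pos = _encounter_positions(rng, k, config.regularity, config.jitter)
        offsets = np.unique(np.round(pos * span).astype(int)) if span else np.array([0])
        dates = [start + dt.timedelta(days=int(t0 + o)) for o in offsets]
        first_dates.append(dates[0])
        for j, d in enumerate(dates):
            dept = "gastroenterology" if j == 0 else _DEPARTMENTS[int(rng.integers(0, len(_DEPARTMENTS)))]
            setting = "inpatient" if rng.random() < 0.7 else "outpatient"
            enc_rows.append((pid, d.isoformat(), dept, setting))
        lang = "fr" if french[i] else "en"
        doc_rows.append(
            (f"{pid}-D000", pid, dates[0].isoformat(), _TEMPLATES[lang], "letter")
        )
        diag_rows.append((pid, "", "K900", dates[0].isoformat()))

    truth_frames: list[pd.DataFrame] = []
    probs_default = None
    for disease in config.diseases:
        case = rng.random(n) < disease.true_prevalence
        fires = _fire_sources(
            rng, n, (disease.p_text, disease.p_icd, disease.p_drug), config.source_correlation
        )
        if config.false_positive_rate > 0.0:
            fp = rng.random((n, 3)) < config.false_positive_rate
            fires = np.where(case[:, None], fires, fp)
        else:
            fires = fires & case[:, None]
        text_f, icd_f, drug_f = fires.T
        mention_fr, mention_en = _MENTIONS.get(disease.dui, (disease.name, disease.name))
        icd_code = _ICD_CODES.get(disease.dui)
        atc_code = _ATC_CODES.get(disease.dui)
        for i in np.flatnonzero(text_f):
            lang = "fr" if french[i] else "en"
            mention = mention_fr if lang == "fr" else mention_en
            doc_rows.append(
                (
                    f"{pids[i]}-{disease.dui}",
                    pids[i],
                    first_dates[i].isoformat(),
                    _MENTION_TEMPLATES[lang].format(mention=mention),
                    "discharge",
                )
            )
        if icd_code is not None:
            for i in np.flatnonzero(icd_f):
                diag_rows.append((pids[i], "", icd_code, first_dates[i].isoformat()))
        if atc_code is not None:
            for i in np.flatnonzero(drug_f):
                rx_rows.append((pids[i], first_dates[i].isoformat(), atc_code))
        truth_frames.append(
            pd.DataFrame({"patient_id": pids, "dui": disease.dui, "case": case})
        )

    bundle = EhrBundle(
        patients=pd.DataFrame(
            {
                "patient_id": pids,
                "sex": sex,
                "age_years": age,
                "registry_member": registry,
            }
        ),
        encounters=pd.DataFrame(enc_rows, columns=["patient_id", "date", "department", "setting"]),
        documents=pd.DataFrame(
            doc_rows, columns=["doc_id", "patient_id", "date", "text", "doc_type"]
        ),
        diagnoses=pd.DataFrame(diag_rows, columns=["patient_id", "encounter_ref", "code", "date"]),
        prescriptions=pd.DataFrame(rx_rows, columns=["patient_id", "date", "code"]),
    ).validate()
    truth = pd.concat(truth_frames, ignore_index=True)
    return bundle, truth


def generate_cooccurrence(
    config: SynthConfig,
    index_dui: str = "D002446",
    subtree_root: str = "C20.111",
    planted_counts: dict[str, int] | None = None,
) -> tuple[dict[str, MeshDescriptor], list[CooccurrenceRecord], list[str]]:
    """Descriptors + co-occurrence records with planted panel signal.

    Panel diseases get synthetic tree addresses under *subtree_root* and
    planted counts taken from the config's disease order (descending by
    construction when using :func:`default_config`'s panel ordering with
    the published counts).  Decoy descriptors live outside the subtree;
    their pairs with the index disease may carry arbitrarily large counts.

    Returns ``(descriptors, records, expected_panel_duis)``.
    """
    rng = np.random.default_rng(config.seed + 1)
    if planted_counts is None:
        tables = fixture_tables()
        counts = dict(zip(tables["panel"]["dui"], tables["panel"]["n_cooccurrence"]))
    else:
        counts = dict(planted_counts)

    descriptors: dict[str, MeshDescriptor] = {
        index_dui: MeshDescriptor(index_dui, "Index Disease", ("C06.405.469.637.250",))
    }
    records: list[CooccurrenceRecord] = []
    expected: list[tuple[str, int]] = []
    for j, disease in enumerate(config.diseases):
        # synthetic positional address under the target subtree
        tree = f"{subtree_root}.{100 + j}"
        descriptors[disease.dui] = MeshDescriptor(disease.dui, disease.name, (tree,))
        count = int(counts.get(disease.dui, rng.integers(1, 50)))
        records.append(CooccurrenceRecord.make(index_dui, disease.dui, count))
        expected.append((disease.dui, count))
    expected.sort(key=lambda m: (-m[1], m[0]))

    for d in range(config.decoy_pairs):
        dui = f"D9{d:05d}"
        tree = f"C{rng.integers(1, 20):02d}.{rng.integers(100, 999)}"
        descriptors[dui] = MeshDescriptor(dui, f"Decoy {d}", (tree,))
        count = int(rng.integers(1, 700))  # may exceed every planted count
        records.append(CooccurrenceRecord.make(index_dui, dui, count))
    # a few decoy-decoy pairs not involving the index disease at all
    decoy_ids = [f"D9{d:05d}" for d in range(min(config.decoy_pairs, 10))]
    for a, b in zip(decoy_ids, decoy_ids[1:]):
        records.append(CooccurrenceRecord.make(a, b, int(rng.integers(1, 700))))

    return descriptors, records, [d for d, _ in expected]


def descriptors_to_text(descriptors: dict[str, MeshDescriptor]) -> str:
    """Serialize descriptors in the package's pipe-delimited dialect."""
    lines = ["dui|name|tree_numbers"]
    for d in descriptors.values():
        lines.append(f"{d.dui}|{d.name}|{';'.join(d.tree_numbers)}")
    return "\n".join(lines) + "\n"


def cooccurrence_to_text(records: list[CooccurrenceRecord]) -> str:
    lines = ["dui_a|dui_b|count"]
    for r in records:
        lines.append(f"{r.dui_a}|{r.dui_b}|{r.count}")
    return "\n".join(lines) + "\n"


def bundle_hash(bundle: EhrBundle) -> str:
    """Stable content hash of a bundle (determinism checks)."""
    h = hashlib.md5()
    for name in ("patients", "encounters", "documents", "diagnoses", "prescriptions"):
        h.update(getattr(bundle, name).to_csv(index=False).encode("utf-8"))
    return h.hexdigest()


def write_simulation(config: SynthConfig, out_dir: str | Path) -> None:
    """Write the five bundle tables, ground truth and literature files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_bundle(config)
    bundle.to_dir(out)
    truth.to_csv(out / "ground_truth.csv", index=False)
    descriptors, records, expected = generate_cooccurrence(config)
    (out / "descriptors.txt").write_text(descriptors_to_text(descriptors), encoding="utf-8")
    (out / "cooccurrence.txt").write_text(cooccurrence_to_text(records), encoding="utf-8")
    pd.DataFrame({"dui": expected}).to_csv(out / "expected_panel.csv", index=False)
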