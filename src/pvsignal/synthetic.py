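"""Synthetic spontaneous-report database with known ground truth.

Generates a FAERS-shaped quarterly file set (DEMO, DRUG, REAC, THER,
OUTC plus a deleted-case list, "$"-delimited ASCII) in which a target
drug carries injected relative-reporting-rate multipliers on chosen
preferred terms.  Every stage of the pipeline — parsing, deduplication,
cohort building, disproportionality, onset timing, subgroups — can
therefore be exercised and validated against the generator's own
bookkeeping without downloading anything.

Event model
-----------
Each case reports each catalog PT independently with probability
``baseline`` (background reports) or ``min(1, baseline * lambda_pt)``
(target-drug reports), the Bernoulli analogue of independent Poisson
counts per (drug, PT) at these small per-report rates.  A case may
draw no PT at all; no top-up draw is made, so marginal frequencies
stay exactly analyzable.

Reproducibility: a single root seed governs everything; per-quarter
streams are spawned sub-streams, so adding quarters never perturbs
earlier ones, and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "GroundTruth", "SyntheticDataset", "generate_dataset", "truth_table", "default_pt_catalog"]

_CASEID_BASE = 10_000_000

#: demographic defaults mirror the composition of a large oncology
#: reporting cohort: about one quarter female / two thirds male,
#: mostly 45+, physicians and consumers the dominant reporters, and a
#: high fraction of serious reports.
DEFAULT_SEX_PROBS = {"F": 0.263, "M": 0.669, "UNK": 0.068}
DEFAULT_AGE_BAND_PROBS = {"<18": 0.011, "18-44": 0.048, "45-64": 0.330, ">=65": 0.418, "unknown": 0.193}
DEFAULT_REPORTER_PROBS = {"MD": 0.34, "CN": 0.28, "OT": 0.15, "PH": 0.08, "LW": 0.01, "UNK": 0.14}
DEFAULT_SERIOUS_PROB = 0.885
#: per-code draw probabilities among serious reports (multi-outcome allowed)
DEFAULT_OUTCOME_PROBS = {"HO": 0.43, "DE": 0.27, "LT": 0.05, "DS": 0.04, "CA": 0.01, "RI": 0.01, "OT": 0.45}

_AGE_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 90)}

DEFAULT_CONCOMITANTS = (
    ("FUROSEMIDE", 0.08),
    ("AMLODIPINE", 0.07),
    ("OMEPRAZOLE", 0.05),
    ("SPIRONOLACTONE", 0.04),
    ("PARACETAMOL", 0.03),
)


def default_pt_catalog(n_pts: int = 200, n_socs: int = 20,
                       min_baseline: float = 0.003, max_baseline: float = 0.1) -> List[Tuple[str, str, float]]:
    """A catalog of PTs with geometrically spaced per-report baselines.

    The defaults give a mean of roughly five events per report, the
    order of magnitude seen in real spontaneous-report databases.
    """
    baselines = np.geomspace(min_baseline, max_baseline, n_pts)
    return [
        (f"PT_{i:03d}", f"SOC_{i % n_socs:02d}", float(baselines[i]))
        for i in range(n_pts)
    ]


@dataclass
class SimConfig:
    """Full specification of one synthetic database."""

    n_background_cases: int = 20000
    n_target_cases: int = 2000
    quarters: Sequence[str] = ("2019Q1", "2019Q2", "2019Q3", "2019Q4")
    pt_catalog: Sequence[Tuple[str, str, float]] = field(default_factory=default_pt_catalog)
    injected_signals: Sequence[Tuple[str, float]] = ()
    duplicate_rate: float = 0.05
    deletion_rate: float = 0.01
    partial_date_rate: float = 0.10
    sex_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_band_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_BAND_PROBS))
    reporter_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTER_PROBS))
    serious_prob: float = DEFAULT_SERIOUS_PROB
    outcome_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    tto_model: Tuple[str, Dict[str, float]] = ("lognormal", {"median": 18.0, "sigma": 1.3})
    target_drug: str = "SORAFENIB"
    concomitant_drugs: Sequence[Tuple[str, float]] = DEFAULT_CONCOMITANTS
    n_background_drugs: int = 50
    secondary_role_rate: float = 0.2
    target_as_concomitant_rate: float = 0.01
    repeat_pt_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_background_cases <= 0 or self.n_target_cases <= 0:
            raise ValueError("case counts must be positive")
        if not self.quarters:
            raise ValueError("at least one quarter is required")
        pts = {pt for pt, _, _ in self.pt_catalog}
        for pt, lam in self.injected_signals:
            if pt not in pts:
                raise ValueError(f"injected signal PT {pt!r} not in pt_catalog")
            if lam < 0:
                raise ValueError("relative reporting multipliers must be >= 0")
        for _, _, p in self.pt_catalog:
            if not 0.0 <= p <= 1.0:
                raise ValueError("baseline probabilities must lie in [0, 1]")
        for name, probs in (
            ("sex_probs", self.sex_probs),
            ("age_band_probs", self.age_band_probs),
            ("reporter_probs", self.reporter_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(not 0 <= v <= 1 for v in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for rate in (self.duplicate_rate, self.deletion_rate, self.partial_date_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        family, _ = self.tto_model
        if family not in ("weibull", "lognormal"):
            raise ValueError("tto_model family must be 'weibull' or 'lognormal'")


@dataclass
class GroundTruth:
    """Generator bookkeeping used by recovery tests downstream."""

    pt_lambda: Dict[str, float]
    target_caseids: List[int]
    duplicate_caseids: List[int]
    deleted_caseids: List[int]
    tto_days: Dict[int, int]  # caseid -> true onset days (pre-corruption)
    counts: Dict[str, Dict[str, int]]  # per-quarter record counts per table
    concomitant_counts: Dict[str, int]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["tto_days"] = {str(k): v for k, v in self.tto_days.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["tto_days"] = {int(k): v for k, v in payload["tto_days"].items()}
        return cls(**payload)


@dataclass
class SyntheticDataset:
    """Paths of the emitted quarterly file set plus the ground truth."""

    directory: Path
    quarters: List[str]
    ground_truth: GroundTruth

    def quarter_paths(self, quarter: str) -> Dict[str, Path]:
        tag = _quarter_tag(quarter)
        return {
            table: self.directory / f"{table.upper()}{tag}.txt"
            for table in ("demo", "drug", "reac", "ther", "outc")
        }

    def deleted_path(self, quarter: str) -> Path:
        return self.directory / f"DELETED{_quarter_tag(quarter)}.txt"

    @property
    def ptsoc_path(self) -> Path:
        return self.directory / "pt_soc_map.tsv"


def _quarter_tag(label: str) -> str:
    year, q = label.split("Q")
    return f"{int(year) % 100:02d}Q{int(q)}"


def _quarter_span(label: str) -> Tuple[_dt.date, int]:
    year, q = int(label.split("Q")[0]), int(label.split("Q")[1])
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    end = _dt.date(year + 1, 1, 1) if q == 4 else _dt.date(year, 3 * q + 1, 1)
    return start, (end - start).days


def _fmt(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def _corrupt(date_str: str, rng: np.random.Generator, rate: float) -> str:
    """Truncate a YYYYMMDD string to month or year precision."""
    if rng.random() >= rate:
        return date_str
    return date_str[:6] if rng.random() < 0.7 else date_str[:4]


def _draw_tto(rng: np.random.Generator, model: Tuple[str, Dict[str, float]], size: int) -> np.ndarray:
    family, params = model
    if family == "lognormal":
        mu = np.log(params["median"])
        vals = rng.lognormal(mean=mu, sigma=params["sigma"], size=size)
    else:
        vals = params["scale"] * rng.weibull(params["shape"], size=size)
    return np.maximum(0, np.round(vals)).astype(int)


def truth_table(ground_truth: GroundTruth) -> pd.DataFrame:
    """Per-PT true multiplier and whether it constitutes a true signal."""
    rows = [
        {"pt": pt, "lambda_true": lam, "is_signal": lam > 1.0}
        for pt, lam in sorted(ground_truth.pt_lambda.items())
    ]
    return pd.DataFrame(rows).set_index("pt")


def generate_dataset(config: SimConfig, outdir: Union[str, Path]) -> SyntheticDataset:
    """Emit the quarterly file set and the ground-truth manifest.

    Fully deterministic given ``config.seed``: re-running with the same
    configuration produces byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    quarters = list(config.quarters)
    nq = len(quarters)
    root = np.random.SeedSequence(config.seed)
    quarter_seeds = root.spawn(nq)

    # deterministic even split of cases across quarters, remainder first
    def _split(total: int) -> List[int]:
        base, rem = divmod(total, nq)
        return [base + (1 if i < rem else 0) for i in range(nq)]

    bg_per_q = _split(config.n_background_cases)
    tg_per_q = _split(config.n_target_cases)
    case_offset = np.concatenate([[0], np.cumsum(np.array(bg_per_q) + np.array(tg_per_q))])

    pts = [pt for pt, _, _ in config.pt_catalog]
    baselines = np.array([p for _, _, p in config.pt_catalog])
    lam = {pt: 1.0 for pt in pts}
    lam.update(dict(config.injected_signals))
    target_probs = np.minimum(1.0, baselines * np.array([lam[pt] for pt in pts]))

    sex_cats, sex_p = zip(*config.sex_probs.items())
    band_cats, band_p = zip(*config.age_band_probs.items())
    rep_cats, rep_p = zip(*config.reporter_probs.items())
    outc_codes = list(config.outcome_probs)
    outc_p = np.array([config.outcome_probs[c] for c in outc_codes])
    bg_drugs = [f"BACKGROUND_DRUG_{i:03d}" for i in range(config.n_background_drugs)]

    gt = GroundTruth(
        pt_lambda=dict(sorted(lam.items())),
        target_caseids=[],
        duplicate_caseids=[],
        deleted_caseids=[],
        tto_days={},
        counts={},
        concomitant_counts={name: 0 for name, _ in config.concomitant_drugs},
    )

    for qi, (label, qseed) in enumerate(zip(quarters, quarter_seeds)):
        rng = np.random.default_rng(qseed)
        n_bg, n_tg = bg_per_q[qi], tg_per_q[qi]
        n = n_bg + n_tg
        caseids = _CASEID_BASE + case_offset[qi] + np.arange(n)
        is_target = np.zeros(n, dtype=bool)
        is_target[n_bg:] = True
        qstart, qdays = _quarter_span(label)

        demo_rows: list = []
        drug_rows: list = []
        reac_rows: list = []
        ther_rows: list = []
        outc_rows: list = []

        # per-case draws
        sexes = rng.choice(sex_cats, size=n, p=sex_p)
        bands = rng.choice(band_cats, size=n, p=band_p)
        reporters = rng.choice(rep_cats, size=n, p=rep_p)
        serious = rng.random(n) < config.serious_prob
        fda_offsets = rng.integers(0, qdays, size=n)
        report_lag = rng.integers(0, 31, size=n)
        ttos = _draw_tto(rng, config.tto_model, n)
        dup_mask = rng.random(n) < config.duplicate_rate
        del_mask = rng.random(n) < config.deletion_rate
        event_mat = rng.random((n, len(pts)))
        age_dec = rng.random(n) < 0.05  # small fraction coded in decades

        deleted_this_q: List[int] = []

        for i in range(n):
            caseid = int(caseids[i])
            primaryid = caseid * 100 + 1
            fda = qstart + _dt.timedelta(days=int(fda_offsets[i]))
            event = fda - _dt.timedelta(days=int(report_lag[i]))
            start = event - _dt.timedelta(days=int(ttos[i]))
            gt.tto_days[caseid] = int(ttos[i])
            if is_target[i]:
                gt.target_caseids.append(caseid)
            if del_mask[i]:
                gt.deleted_caseids.append(caseid)
                deleted_this_q.append(caseid)

            band = bands[i]
            if band == "unknown":
                age, age_cod = "", ""
            else:
                lo, hi = _AGE_RANGES[band]
                years = int(rng.integers(lo, hi + 1))
                if age_dec[i]:
                    age, age_cod = f"{years / 10:.1f}", "DEC"
                else:
                    age, age_cod = str(years), "YR"

            event_str = _corrupt(_fmt(event), rng, config.partial_date_rate)
            start_str = _corrupt(_fmt(start), rng, config.partial_date_rate)
            occp = "" if reporters[i] == "UNK" else reporters[i]
            sex = "" if sexes[i] == "UNK" else sexes[i]

            versions = [(primaryid, _fmt(fda))]
            if dup_mask[i]:
                gt.duplicate_caseids.append(caseid)
                follow_up = fda + _dt.timedelta(days=int(rng.integers(1, 91)))
                versions.append((caseid * 100 + 2, _fmt(follow_up)))

            # events: one REAC row per distinct (case, PT)
            probs = target_probs if is_target[i] else baselines
            hit = np.nonzero(event_mat[i] < probs)[0]
            case_pts = [pts[j] for j in hit]
            if config.repeat_pt_rate > 0 and case_pts and rng.random() < config.repeat_pt_rate:
                case_pts = case_pts + [case_pts[0]]  # exercised by within-case dedup tests

            # drug mentions
            mentions: List[Tuple[int, str, str, str]] = []  # (seq, role, name, ai)
            if is_target[i]:
                mentions.append((1, "PS", config.target_drug, config.target_drug))
                for name, prob in config.concomitant_drugs:
                    if rng.random() < prob:
                        mentions.append((len(mentions) + 1, "C", name, name))
                        gt.concomitant_counts[name] += 1
            else:
                name = bg_drugs[int(rng.integers(len(bg_drugs)))]
                mentions.append((1, "PS", name, name))
                if rng.random() < config.secondary_role_rate:
                    extra = bg_drugs[int(rng.integers(len(bg_drugs)))]
                    role = "SS" if rng.random() < 0.5 else "C"
                    mentions.append((2, role, extra, extra))
                if rng.random() < config.target_as_concomitant_rate:
                    mentions.append((len(mentions) + 1, "C", config.target_drug, config.target_drug))

            codes: List[str] = []
            if serious[i]:
                draw = rng.random(len(outc_codes)) < outc_p
                codes = [c for c, hit_ in zip(outc_codes, draw) if hit_]
                if not any(c in ("DE", "LT", "HO", "DS", "CA", "RI") for c in codes):
                    codes.append("HO")
            elif rng.random() < 0.5:
                codes = ["OT"]

            for pid, fda_str in versions:
                demo_rows.append((pid, caseid, fda_str, event_str, age, age_cod, sex, occp))
                for seq, role, name, ai in mentions:
                    drug_rows.append((pid, caseid, seq, role, name, ai))
                    ther_rows.append((pid, caseid, seq, start_str))
                for pt in case_pts:
                    reac_rows.append((pid, caseid, pt))
                for code in codes:
                    outc_rows.append((pid, caseid, code))

        tag = _quarter_tag(label)
        frames = {
            "demo": pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex", "occp_cod"]),
            "drug": pd.DataFrame(drug_rows, columns=["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"]),
            "reac": pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"]),
            "ther": pd.DataFrame(ther_rows, columns=["primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
            "outc": pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"]),
        }
        for table, frame in frames.items():
            frame.to_csv(outdir / f"{table.upper()}{tag}.txt", sep="$", index=False)
        (outdir / f"DELETED{tag}.txt").write_text(
            "".join(f"{cid}\n" for cid in deleted_this_q)
        )
        gt.counts[label] = {table: len(frame) for table, frame in frames.items()}
        gt.counts[label]["deleted"] = len(deleted_this_q)

    # PT -> SOC companion map for SOC-level analyses
    ptsoc = pd.DataFrame(
        [(pt, soc, 1) for pt, soc, _ in config.pt_catalog],
        columns=["pt", "soc", "primary_flag"],
    )
    ptsoc.to_csv(outdir / "pt_soc_map.tsv", sep="\t", index=False)

    gt.target_caseids.sort()
    gt.duplicate_caseids.sort()
    gt.deleted_caseids.sort()
    gt.to_json(outdir / "ground_truth.json")
    return SyntheticDataset(directory=outdir, quarters=quarters, ground_truth=gt)
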