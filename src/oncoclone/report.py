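"""Cohort aggregation: sharing tables, contingency statistics, actionable
events, and the end-to-end pipeline driver.

Percentages are printed to one decimal with round-half-up, chi-squared
statistics are Pearson without continuity correction, and group
comparisons use the Mann–Whitney U test (exact for small tie-free samples).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import SHARING_CATEGORIES

log = logging.getLogger(__name__)

EVENT_TYPES = ("mutation", "cnv")


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SharingTable:
    """Counts and percentages of shared/private events by event type."""

    counts: dict[str, dict[str, int]]  # event type -> category -> count

    def total(self, event_type: str) -> int:
        return sum(self.counts[event_type].values())

    def percentages(self, event_type: str) -> dict[str, float]:
        total = self.total(event_type)
        if total == 0:
            return {c: 0.0 for c in SHARING_CATEGORIES}
        return {
            c: _round1(100.0 * self.counts[event_type][c] / total)
            for c in SHARING_CATEGORIES
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for et in EVENT_TYPES:
            pct = self.percentages(et)
            for cat in SHARING_CATEGORIES:
                rows.append(dict(event_type=et, category=cat,
                                 count=self.counts[et][cat], percent=pct[cat]))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActionableEvent:
    gene: str
    event: str  # mutation | amplification | deletion
    category: str  # sharing category
    note: str


def tabulate_sharing(
    events: Sequence[tuple[str, str]] | Mapping[str, Mapping[str, int]],
) -> SharingTable:
    """Build the sharing table from (event_type, category) pairs or counts."""
    counts = {et: {c: 0 for c in SHARING_CATEGORIES} for et in EVENT_TYPES}
    if isinstance(events, Mapping):
        for et, cats in events.items():
            for cat, n in cats.items():
                if et not in counts or cat not in counts[et]:
                    raise ValueError(f"unknown event type/category ({et}, {cat})")
                counts[et][cat] = int(n)
    else:
        for et, cat in events:
            if et not in counts or cat not in counts[et]:
                raise ValueError(f"unknown event type/category ({et}, {cat})")
            counts[et][cat] += 1
    return SharingTable(counts)


def compare_proportions(
    table: np.ndarray, mode: str = "per_category_2x2"
) -> tuple[float, float, int]:
    """Pearson chi-squared (no continuity correction) on a contingency table.

    Returns (statistic, p, dof). Expected cells below 1 abort with advice
    to use an exact test.
    """
    table = np.asarray(table, dtype=float)
    if mode not in ("per_category_2x2", "overall_2x3"):
        raise ValueError(f"unknown mode {mode!r}")
    expected = stats.contingency.expected_freq(table)
    if (expected < 1.0).any():
        raise ValueError("expected cell below 1; use an exact test")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact distribution when the smaller group has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one value")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def load_actionable_table() -> pd.DataFrame:
    """The packaged actionable-gene table (gene, event, note)."""
    path = resources.files("oncoclone").joinpath("data/actionable_genes.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if list(df.columns) != ["gene", "event", "note"]:
        raise ValueError("malformed actionable table")
    return df


def annotate_actionable(
    events: Sequence[tuple[str, str, str]],
    table: pd.DataFrame | None = None,
) -> list[ActionableEvent]:
    """Match (gene, event type, sharing category) events against the table.

    Event types are mutation / amplification / deletion; genes absent from
    the table are ignored.
    """
    if table is None:
        table = load_actionable_table()
    if table.isna().any().any():
        raise ValueError("malformed actionable table row (missing fields)")
    lookup = {(r.gene, r.event): r.note for r in table.itertuples()}
    out = []
    for gene, etype, category in events:
        note = lookup.get((gene, etype))
        if note is not None:
            out.append(ActionableEvent(gene, etype, category, note))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver


def analyse_patient(
    patient,
    k_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    presence_threshold: float = 0.05,
    tolerance: float = 0.1,
) -> dict:
    """Run clustering, tree building and progression calling on one patient.

    ``patient`` is any object with regions / variants / observations /
    segments plus ``count_matrices()`` (a SimulatedPatient, or the
    equivalent assembled from files). Returns a dict of stage outputs.
    """
    from .clustering import cluster_mutations, cluster_table
    from .phylogeny import build_tree, detect_msai, detect_parallel_snv, molecular_time

    alt, depth, f = patient.count_matrices()
    vids = [v.variant_id for v in patient.variants]
    fit = cluster_mutations(alt, depth, f, variant_ids=vids,
                            region_ids=tuple(patient.region_ids),
                            k_range=k_range, seed=seed)
    result: dict = {"fit": fit, "clusters": cluster_table(fit)}
    assignments = {vid: int(c) for vid, c in zip(vids, fit.assignments)}
    result["assignments"] = assignments
    try:
        tree = build_tree(fit.clusters, tolerance=tolerance)
        result["tree"] = tree
        result["parallel_events"] = detect_parallel_snv(patient.variants, assignments, tree)
    except Exception as exc:  # degenerate fits on noisy patients
        log.warning("%s: tree building failed (%s)", patient.patient_id, exc)
        result["tree"] = None
        result["parallel_events"] = []
    result["progression"] = molecular_time(
        result["tree"], fit.clusters, patient.regions,
        patient_id=patient.patient_id,
        presence_threshold=presence_threshold,
    )
    result["msai_events"] = detect_msai(patient.segments)
    return result


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline from a YAML config; returns the report dir.

    The config lists patients (either files or a simulation block), stage
    toggles and the seed; all parameter values in force are logged to
    ``parameters.json`` in the report directory.
    """
    import yaml

    from .simdata import SimConfig, simulate_cohort, write_patient

    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(out_dir or cfg.get("out_dir", "oncoclone_report"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", {})

    def stage_on(name: str) -> bool:
        return bool(stages.get(name, True))

    sim = cfg.get("simulate", {})
    sim_args = {k: v for k, v in sim.items() if k not in ("n_patients",)}
    if "purity_range" in sim_args:
        sim_args["purity_range"] = tuple(sim_args["purity_range"])
    sconfig = SimConfig(seed=seed, **sim_args)
    patients = simulate_cohort(int(sim.get("n_patients", 6)), sconfig, seed=seed)

    summaries = []
    sharing_events = []
    for patient in patients:
        pdir = out / patient.patient_id
        write_patient(patient, pdir)
        if not stage_on("cluster"):
            continue
        res = analyse_patient(patient, seed=seed)
        res["clusters"].to_csv(pdir / "clusters.tsv", sep="\t", index=False)
        if res["tree"] is not None:
            (pdir / "tree.nwk").write_text(res["tree"].to_newick() + "\n")
            (pdir / "tree.json").write_text(res["tree"].to_parent_json() + "\n")
        prog = res["progression"]
        summaries.append(
            dict(
                patient_id=patient.patient_id,
                n_clusters=res["fit"].k,
                molecular_time_pct=prog.molecular_time_pct,
                model=prog.model,
                n_parallel_events=len(res["parallel_events"]),
                n_msai_events=len(res["msai_events"]),
            )
        )
        if stage_on("sharing"):
            from .ccf import ccf_table

            table = ccf_table(patient.variants, patient.observations, patient.regions)
            table.to_csv(pdir / "ccf.tsv", sep="\t", index=False)
            per_variant = table.drop_duplicates("variant_id")
            sharing_events.extend(("mutation", cat) for cat in per_variant["sharing"])

    summary = pd.DataFrame(summaries)
    summary.to_csv(out / "patients.tsv", sep="\t", index=False)
    if sharing_events:
        tabulate_sharing(sharing_events).to_frame().to_csv(
            out / "sharing.tsv", sep="\t", index=False
        )
    (out / "parameters.json").write_text(
        json.dumps({"seed": seed, "simulate": sim, "stages": stages}, indent=1)
    )
    log.info("report written to %s", out)
    return out
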