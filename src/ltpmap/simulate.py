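"""Synthetic two-region cohorts with known ground truth.

No raw serum measurements are deposited with the study this package
re-analyzes, so end-to-end behavior is exercised on simulated cohorts
whose parameters are the published summary statistics themselves: cohort
sizes of 55 (USA) and 17 (Spain); per-peptide positivity prevalences
equal to the published percentages for all 51 protein/peptide pairs; and
intact-protein (ISAC) positivity rates of about 2% in the US versus
71/65/76% in Spain for Ara h 9/Jug r 3/Pru p 3.

Generative model, per subject: each peptide's true positivity is an
independent Bernoulli draw at the cohort prevalence (no subject-level
random effect by default — the published data give no correlation
structure; an optional subject reactivity multiplier is available).
Spot-level SNRs are log-normal, drawn independently per replicate:
positive spots have median 7 (within the 5-9 range of the published
per-peptide medians), negative spots median 1, both with log-scale
dispersion 0.5, under which the median of triplicates misclassifies well
under 1% of spots at the SNR >= 3 threshold. Each replicate drops out
independently with probability 0.02 (never all three, unless the guard
is disabled). ISU-E values are log-normal with median 2 for binders and
uniform jitter below 0.3 for non-binders.

All draws come from one seeded generator in a documented order (subjects
-> peptides -> replicates -> ISAC), so cohorts are bit-reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .signal import BindingMatrix, IsacRecord, SpotRecord


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic two-region cohort.

    ``prevalence`` maps region -> protein -> per-peptide positivity
    probabilities; ``isac_rates`` maps region -> allergen -> probability
    of intact-protein binding.
    """

    n_subjects: dict[str, int]
    prevalence: dict[str, dict[str, tuple[float, ...]]]
    isac_rates: dict[str, dict[str, float]]
    positive_snr_median: float = 7.0
    negative_snr_median: float = 1.0
    snr_log_sd: float = 0.5
    replicate_count: int = 3
    dropout_probability: float = 0.02
    keep_at_least_one_replicate: bool = True
    subject_effect_log_sd: float = 0.0  # optional subject reactivity multiplier
    isac_binder_median: float = 2.0
    isac_binder_log_sd: float = 0.8
    isac_nonbinder_max: float = 0.25

    def __post_init__(self) -> None:
        for region, n in self.n_subjects.items():
            if n <= 0:
                raise SimulationError(f"region {region!r} must have > 0 subjects")
        for region, per_protein in self.prevalence.items():
            for protein, probs in per_protein.items():
                arr = np.asarray(probs, dtype=float)
                if np.any((arr < 0) | (arr > 1)):
                    raise SimulationError(
                        f"prevalence outside [0,1] for {region}/{protein}")
        for region, rates in self.isac_rates.items():
            for allergen, p in rates.items():
                if not 0 <= p <= 1:
                    raise SimulationError(
                        f"ISAC rate outside [0,1] for {region}/{allergen}")
        if not 0 <= self.dropout_probability <= 1:
            raise SimulationError("dropout_probability outside [0,1]")


@dataclass
class SyntheticCohort:
    """Simulated spot + ISAC records with ground truth and provenance."""

    spec: CohortSpec
    seed: int
    spots: pd.DataFrame          # subject_id, region, protein, peptide_index, replicate, snr
    isac: pd.DataFrame           # subject_id, region, allergen, isu_e
    truth_peptides: pd.DataFrame  # subject_id, region, protein, peptide_index, truly_positive
    truth_isac: pd.DataFrame     # subject_id, region, allergen, binder

    def spot_records(self) -> list[SpotRecord]:
        return [
            SpotRecord(
                subject_id=r.subject_id, region_label=r.region, protein=r.protein,
                peptide_index=int(r.peptide_index),
                replicate_ordinal=int(r.replicate), snr=float(r.snr),
            )
            for r in self.spots.itertuples(index=False)
        ]

    def isac_records(self) -> list[IsacRecord]:
        lo, hi = 0.3, 100.0
        return [
            IsacRecord(
                subject_id=r.subject_id, region_label=r.region,
                allergen=r.allergen, isu_e=float(r.isu_e),
                out_of_range=not (lo <= float(r.isu_e) <= hi),
            )
            for r in self.isac.itertuples(index=False)
        ]

    def binding_matrix(self) -> BindingMatrix:
        """Median-over-replicates matrix computed directly (vectorized)."""
        regions = self.spots.groupby("subject_id")["region"].first()
        values = {}
        for protein, sub in self.spots.groupby("protein"):
            med = sub.groupby(["subject_id", "peptide_index"])["snr"].median().unstack()
            med = med.reindex(regions.index)
            med.columns = med.columns.astype(int)
            values[str(protein)] = med.sort_index(axis=1)
        return BindingMatrix(values=values, regions=regions)


def default_cohort_spec(scale_subjects: dict[str, int] | None = None) -> CohortSpec:
    """The study-calibrated cohort specification.

    Prevalences are the published per-peptide percentages divided by 100
    for all 51 protein/peptide pairs in both regions; ISAC rates are the
    published intact-binding percentages. ``scale_subjects`` optionally
    overrides the cohort sizes (e.g. for parameter-recovery checks at
    larger n) without touching the probabilities.
    """
    sizes = dict(scale_subjects or reference.COHORT_SIZES)
    prevalence: dict[str, dict[str, tuple[float, ...]]] = {"USA": {}, "Spain": {}}
    for protein, pairs in reference.PREVALENCE_COUNTS.items():
        prevalence["USA"][protein] = tuple(
            us / reference.COHORT_SIZES["USA"] for us, _ in pairs)
        prevalence["Spain"][protein] = tuple(
            sp / reference.COHORT_SIZES["Spain"] for _, sp in pairs)
    return CohortSpec(
        n_subjects=sizes,
        prevalence=prevalence,
        isac_rates={r: dict(v) for r, v in reference.ISAC_POSITIVE_RATES.items()},
    )


def null_cohort_spec(scale_subjects: dict[str, int] | None = None) -> CohortSpec:
    """A no-regional-difference spec: both regions share the US prevalences."""
    spec = default_cohort_spec(scale_subjects)
    prevalence = {
        "USA": dict(spec.prevalence["USA"]),
        "Spain": dict(spec.prevalence["USA"]),
    }
    return replace(spec, prevalence=prevalence)


def generate_cohort(spec: CohortSpec, seed: int) -> SyntheticCohort:
    """Draw a complete synthetic cohort from ``spec``.

    Deterministic given (spec, seed). Subjects are drawn region by region
    in the declared order; within a subject, peptide truths, then
    replicate SNRs, then dropout; ISAC values last.
    """
    rng = np.random.default_rng(seed)
    regions = list(spec.n_subjects)
    subj_rows = []
    for region in regions:
        for i in range(spec.n_subjects[region]):
            subj_rows.append((f"{region}_{i + 1:03d}", region))

    spot_frames = []
    truth_frames = []
    for subject_id, region in subj_rows:
        subject_factor = (
            float(np.exp(rng.normal(0.0, spec.subject_effect_log_sd)))
            if spec.subject_effect_log_sd > 0 else 1.0
        )
        for protein, probs in spec.prevalence[region].items():
            probs = np.asarray(probs, dtype=float)
            n_pep = probs.size
            truth = rng.random(n_pep) < probs
            medians = np.where(
                truth, spec.positive_snr_median * subject_factor,
                spec.negative_snr_median,
            )
            snr = np.exp(
                np.log(medians)[:, None]
                + rng.normal(0.0, spec.snr_log_sd, size=(n_pep, spec.replicate_count))
            )
            keep = rng.random((n_pep, spec.replicate_count)) >= spec.dropout_probability
            if spec.keep_at_least_one_replicate:
                lost = ~keep.any(axis=1)
                keep[lost, 0] = True
            pep_idx, rep_idx = np.nonzero(keep)
            spot_frames.append(pd.DataFrame(
                {"subject_id": subject_id, "region": region, "protein": protein,
                 "peptide_index": pep_idx + 1, "replicate": rep_idx + 1,
                 "snr": snr[pep_idx, rep_idx]}
            ))
            truth_frames.append(pd.DataFrame(
                {"subject_id": subject_id, "region": region, "protein": protein,
                 "peptide_index": np.arange(1, n_pep + 1),
                 "truly_positive": truth}
            ))

    isac_rows = []
    truth_isac_rows = []
    for subject_id, region in subj_rows:
        for allergen, rate in spec.isac_rates[region].items():
            binder = bool(rng.random() < rate)
            if binder:
                isu = float(np.exp(np.log(spec.isac_binder_median)
                                   + rng.normal(0.0, spec.isac_binder_log_sd)))
            else:
                isu = float(rng.uniform(0.0, spec.isac_nonbinder_max))
            isac_rows.append(
                {"subject_id": subject_id, "region": region,
                 "allergen": allergen, "isu_e": isu})
            truth_isac_rows.append(
                {"subject_id": subject_id, "region": region,
                 "allergen": allergen, "binder": binder})

    empty_spots = pd.DataFrame(
        columns=["subject_id", "region", "protein", "peptide_index",
                 "replicate", "snr"])
    return SyntheticCohort(
        spec=spec,
        seed=seed,
        spots=(pd.concat(spot_frames, ignore_index=True)
               if spot_frames else empty_spots),
        isac=pd.DataFrame(isac_rows),
        truth_peptides=(pd.concat(truth_frames, ignore_index=True)
                        if truth_frames else pd.DataFrame(
                            columns=["subject_id", "region", "protein",
                                     "peptide_index", "truly_positive"])),
        truth_isac=pd.DataFrame(truth_isac_rows),
    )


def cohort_from_counts(
    counts: dict[str, list[tuple[int, int]]] | None = None,
    cohort_sizes: dict[str, int] | None = None,
    positive_snr: float = 8.0,
    negative_snr: float = 1.0,
    replicate_count: int = 3,
) -> SyntheticCohort:
    """Deterministic cohort whose positive-call counts match given counts.

    For each (protein, peptide, region) exactly ``n_positive`` subjects —
    the first ones in subject order — receive well-separated positive
    SNRs; the rest receive negative SNRs. Replicates are exact copies, so
    the median equals the assigned value and the downstream calls
    reproduce the counts identically. Defaults to the published count
    table.
    """
    counts = counts or reference.PREVALENCE_COUNTS
    cohort_sizes = cohort_sizes or dict(reference.COHORT_SIZES)
    regions = list(cohort_sizes)
    frames = []
    truth_frames = []
    for region_pos, region in enumerate(regions):
        n_sub = cohort_sizes[region]
        for protein, pairs in counts.items():
            for pep_idx, tup in enumerate(pairs, start=1):
                n_pos = tup[region_pos]
                if n_pos > n_sub:
                    raise SimulationError(
                        f"count {n_pos} exceeds cohort size {n_sub} for {region}")
                for s in range(n_sub):
                    snr = positive_snr if s < n_pos else negative_snr
                    for rep in range(1, replicate_count + 1):
                        frames.append(
                            (f"{region}_{s + 1:03d}", region, protein, pep_idx,
                             rep, snr))
                    truth_frames.append(
                        (f"{region}_{s + 1:03d}", region, protein, pep_idx,
                         s < n_pos))
    spots = pd.DataFrame(
        frames, columns=["subject_id", "region", "protein", "peptide_index",
                         "replicate", "snr"])
    truth = pd.DataFrame(
        truth_frames, columns=["subject_id", "region", "protein",
                               "peptide_index", "truly_positive"])
    spec = default_cohort_spec(cohort_sizes)
    return SyntheticCohort(
        spec=spec, seed=0, spots=spots,
        isac=pd.DataFrame(columns=["subject_id", "region", "allergen", "isu_e"]),
        truth_peptides=truth,
        truth_isac=pd.DataFrame(columns=["subject_id", "region", "allergen", "binder"]),
    )


def write_fixtures(cohort: SyntheticCohort, destination: str | Path) -> dict[str, Path]:
    """Write spot, ISAC and ground-truth TSVs readable by the ingestion layer.

    The truth file carries the seed; a sidecar spec file records the
    generative parameters.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": dest / "spots.tsv",
        "isac": dest / "isac.tsv",
        "truth_peptides": dest / "truth_peptides.tsv",
        "truth_isac": dest / "truth_isac.tsv",
        "spec": dest / "cohort_spec.yaml",
    }
    cohort.spots.to_csv(paths["spots"], sep="\t", index=False)
    cohort.isac.to_csv(paths["isac"], sep="\t", index=False)
    truth = cohort.truth_peptides.copy()
    truth["seed"] = cohort.seed
    truth.to_csv(paths["truth_peptides"], sep="\t", index=False)
    cohort.truth_isac.to_csv(paths["truth_isac"], sep="\t", index=False)
    import yaml

    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(
            {"seed": cohort.seed,
             "n_subjects": dict(cohort.spec.n_subjects),
             "positive_snr_median": cohort.spec.positive_snr_median,
             "negative_snr_median": cohort.spec.negative_snr_median,
             "snr_log_sd": cohort.spec.snr_log_sd,
             "replicate_count": cohort.spec.replicate_count,
             "dropout_probability": cohort.spec.dropout_probability,
             "isac_rates": {k: dict(v) for k, v in cohort.spec.isac_rates.items()},
             "prevalence": {
                 region: {p: list(map(float, v)) for p, v in per.items()}
                 for region, per in cohort.spec.prevalence.items()},
             }, fh, sort_keys=False)
    return paths
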