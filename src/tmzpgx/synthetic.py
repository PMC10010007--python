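"""Synthetic study generator with recorded ground truth.

Every downstream stage of the pipeline is testable without controlled-access
patient data because this module generates a full synthetic study around a
latent per-patient sensitivity label: screening plates whose GR50 values are
drawn from a bimodal log-normal (high mode = resistant), negative-binomial
expression counts with the four resistance-marker genes up-regulated in
resistant patients and subtype signature genes spiked per latent subtype,
log2-ratio copy-number profiles in which the concurrent PTEN / EGFR /
CDKN2A/B lesion triple is enriched in sensitive patients, somatic variant
tables with driver enrichment plus filterable chaff, exponential survival
times with a configurable resistant-vs-sensitive hazard ratio, and
multi-sector patients with mixed sector labels.

Default effect sizes follow the study conditions: hazard ratio 2.75, marker
effect above the 2.5 log2-fold-change selection cutoff, resistant fraction
29/69, GR50 modes separated by about five within-mode standard deviations
on the log scale.  A single seeded generator is threaded through all
sub-simulators, so a fixed seed reproduces the bundle bitwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .drug_response import (
    DEFAULT_CONCENTRATIONS_UM,
    DEFAULT_SEEDING_SIGNAL,
    DoseResponsePlate,
)
from .genomic import call_cna_class
from .multisector import MultiSectorPatient

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CohortBundle",
    "simulate_cohort",
    "simulate_dose_response",
    "simulate_expression_counts",
    "simulate_multisector",
    "build_feature_sources",
    "write_bundle",
    "MARKER_GENES",
]

MARKER_GENES = ("EGR4", "PAPPA", "LRRC3", "ANXA3")
DRIVER_SNV_GENES = ("NF1", "PTEN", "TP53", "EGFR", "PIK3R1", "PIK3CA", "RB1")
CNA_GENES = ("PTEN", "EGFR", "CDKN2A/B", "PDGFRA", "CDK4", "MDM2")
SUBTYPES = ("classical", "proneural", "mesenchymal")

#: log2-ratio centres used when materialising a true CNA class.
CLASS_CENTERS = {
    "deletion": -2.0,
    "loss": -1.0,
    "neutral": 0.0,
    "gain": 1.0,
    "amplification": 2.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_patients: int = 69
    resistant_fraction: float = 29 / 69
    gr50_means: tuple[float, float] = (300.0, 8.0)  # uM (resistant, sensitive)
    gr50_cv: float = 0.8  # ~5 SD mode separation on the log scale
    marker_log2fc: float = 3.0  # above the 2.5 selection cutoff
    concurrent_cna_rates: dict = field(
        default_factory=lambda: {"resistant": 0.1, "sensitive": 0.45}
    )
    survival_hr: float = 2.75  # resistant vs sensitive
    censor_rate: float = 0.2
    missing_rate: float = 0.1
    n_genes: int = 2000
    dispersion: float = 0.1
    subtype_log2fc: float = 2.0
    plate_noise_sd: float = 0.05
    cna_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("resistant_fraction", "censor_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name}={v} outside [0, 1]")
        if self.n_patients < 2:
            raise ValueError("config field n_patients must be >= 2")
        if any(m <= 0 for m in self.gr50_means):
            raise ValueError("config field gr50_means must be positive")
        if self.survival_hr <= 0:
            raise ValueError("config field survival_hr must be positive")
        for name in ("gr50_cv", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name} must be nonnegative")
        for cls, rate in self.concurrent_cna_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(
                    f"config field concurrent_cna_rates[{cls}]={rate} outside [0, 1]"
                )


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated bundle."""

    labels: pd.Series  # resistant / sensitive per patient
    gr50: pd.Series  # true GR50 (uM) per patient
    subtype: pd.Series  # true transcriptional subtype per patient
    cna_classes: pd.DataFrame  # genes x patients, five-level classes
    marker_genes: tuple[str, ...]
    concurrent_cna: pd.Series  # bool per patient
    mgmt_methylated: pd.Series  # bool per patient

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels.to_dict(),
                "gr50": self.gr50.round(6).to_dict(),
                "subtype": self.subtype.to_dict(),
                "cna_classes": {
                    g: self.cna_classes.loc[g].to_dict()
                    for g in self.cna_classes.index
                },
                "marker_genes": list(self.marker_genes),
                "concurrent_cna": {
                    k: bool(v) for k, v in self.concurrent_cna.items()
                },
                "mgmt_methylated": {
                    k: bool(v) for k, v in self.mgmt_methylated.items()
                },
            },
            sort_keys=True,
        )


@dataclass
class CohortBundle:
    """The observable tables a real study would yield."""

    plates: list[DoseResponsePlate]
    variants: pd.DataFrame  # sample_id, gene, effect_class, vaf_tumor, vaf_blood
    counts: pd.DataFrame  # genes x patients (tumor tissue RNA)
    gene_lengths: pd.Series
    cna_log2: pd.DataFrame  # genes x patients
    clinical: pd.DataFrame  # survival + covariates per patient
    gene_sets: dict[str, list[str]]  # subtype signature sets
    egfrviii_reads: pd.Series  # exon 2-7 skip-read counts per patient


def _gec50_from_gr50(gr50: float, grinf: float, hill: float) -> float:
    ratio = (1.0 - grinf) / (0.5 - grinf) - 1.0
    return gr50 / ratio ** (1.0 / hill)


def simulate_dose_response(
    gr50: float,
    grinf: float,
    hill: float,
    concentrations=DEFAULT_CONCENTRATIONS_UM,
    noise_sd: float = 0.0,
    sample_id: str = "S",
    rng: np.random.Generator | None = None,
    control_signal: float = 4000.0,
    t0_signal: float = DEFAULT_SEEDING_SIGNAL,
) -> DoseResponsePlate:
    """Plate readouts implied by a GR sigmoid, with log-normal noise.

    The curve is parametrised by its GR50 (requires grinf < 0.5); the
    treated signal at concentration c is x0 * (xctrl/x0)^log2(GR(c)+1),
    multiplied by exp(N(0, noise_sd)) noise.  The default concentration
    grid is the seven-point fourfold dilution series from 500 uM down to
    0.122 uM.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not grinf < 0.5:
        raise ValueError("generation from a GR50 requires grinf < 0.5")
    if hill <= 0:
        raise ValueError("hill slope must be positive")
    rng = rng or np.random.default_rng(0)

    gec50 = _gec50_from_gr50(gr50, grinf, hill)
    gr = grinf + (1.0 - grinf) / (1.0 + (conc / gec50) ** hill)
    log_ratio = np.log2(control_signal / t0_signal)
    viability = t0_signal * (control_signal / t0_signal) ** np.log2(gr + 1.0)
    if noise_sd > 0:
        viability = viability * np.exp(rng.normal(0.0, noise_sd, size=conc.size))
    return DoseResponsePlate(
        sample_id=sample_id,
        concentrations=conc,
        viability=viability,
        control_signal=control_signal,
        t0_signal=t0_signal,
    )


def simulate_expression_counts(
    n_genes: int,
    group_sizes: tuple[int, int],
    spiked_genes: dict[int, float] | None = None,
    dispersion: float = 0.1,
    base_mean_log: tuple[float, float] = (4.5, 1.0),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix for two groups.

    ``spiked_genes`` maps gene row index -> log2 fold change applied in the
    first group.  Returns (counts genes x samples, labels: 'a' for the first
    group, 'b' for the second).  Used directly by the differential-expression
    power/null simulations.
    """
    rng = rng or np.random.default_rng(0)
    n_a, n_b = group_sizes
    base = np.exp(rng.normal(*base_mean_log, size=n_genes))
    mu = np.tile(base[:, None], (1, n_a + n_b))
    for idx, lfc in (spiked_genes or {}).items():
        mu[idx, :n_a] *= 2.0**lfc
    counts = _nb_sample(mu, dispersion, rng)
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    labels = pd.Series(["a"] * n_a + ["b"] * n_b, index=cols)
    return pd.DataFrame(counts, columns=cols), labels


def _nb_sample(mu: np.ndarray, dispersion: float, rng: np.random.Generator):
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_multisector(
    n_patients: int,
    sectors_per_patient,
    het_fraction: float,
    seed: int = 0,
) -> list[MultiSectorPatient]:
    """Multi-sector patients, a het_fraction of whom get mixed labels.

    ``sectors_per_patient`` is either one integer in {2,3,4} for all
    patients or a sequence of per-patient counts.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(sectors_per_patient):
        sector_counts = [int(sectors_per_patient)] * n_patients
    else:
        sector_counts = [int(s) for s in sectors_per_patient]
        if len(sector_counts) != n_patients:
            raise ValueError("one sector count per patient required")
    if any(s not in (2, 3, 4) for s in sector_counts):
        raise ValueError("sector counts must be in {2, 3, 4}")

    n_het = int(round(het_fraction * n_patients))
    het_ids = set(rng.choice(n_patients, size=n_het, replace=False).tolist())
    patients = []
    for i, n_sec in enumerate(sector_counts):
        if i in het_ids:
            n_res = int(rng.integers(1, n_sec))  # both labels present
            labels = ["resistant"] * n_res + ["sensitive"] * (n_sec - n_res)
            labels = [labels[j] for j in rng.permutation(n_sec)]
        else:
            labels = [
                "resistant" if rng.random() < 0.5 else "sensitive"
            ] * n_sec
        patients.append(MultiSectorPatient(f"M{i + 1}", tuple(labels)))
    return patients


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate the full observable bundle plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    pid = pd.Index(ids, name="sample_id")

    labels = pd.Series(
        np.where(
            rng.random(config.n_patients) < config.resistant_fraction,
            "resistant",
            "sensitive",
        ),
        index=pid,
        name="label",
    )
    resistant = (labels == "resistant").values

    # --- dose-response: bimodal log-normal GR50 tied to the label
    sigma_ln = math.sqrt(math.log(1.0 + config.gr50_cv**2))
    mode = np.where(resistant, config.gr50_means[0], config.gr50_means[1])
    gr50 = pd.Series(
        mode * np.exp(rng.normal(0.0, sigma_ln, config.n_patients)),
        index=pid,
        name="gr50_um",
    )
    grinf = np.where(resistant, 0.1, -0.3)
    plates = [
        simulate_dose_response(
            gr50[s],
            grinf[i],
            hill=2.0,
            noise_sd=config.plate_noise_sd,
            sample_id=s,
            rng=rng,
        )
        for i, s in enumerate(ids)
    ]

    # --- gene universe: named drivers/markers + anonymous filler
    named = list(MARKER_GENES) + ["MGMT"] + list(CNA_GENES) + [
        g for g in DRIVER_SNV_GENES if g not in CNA_GENES
    ]
    named = list(dict.fromkeys(named))
    n_filler = max(config.n_genes - len(named), 0)
    genes = named + [f"G{i + 1:05d}" for i in range(n_filler)]
    gene_lengths = pd.Series(
        rng.integers(500, 5000, size=len(genes)).astype(float),
        index=pd.Index(genes, name="gene"),
        name="length_bp",
    )

    # --- subtype truth and signature sets (30 filler genes per subtype)
    subtype = pd.Series(
        rng.choice(SUBTYPES, size=config.n_patients), index=pid, name="subtype"
    )
    filler = genes[len(named):]
    gene_sets = {
        f"signature_{st}": filler[30 * i: 30 * (i + 1)]
        for i, st in enumerate(SUBTYPES)
    }

    # --- MGMT promoter methylation: associated with sensitivity
    p_meth = np.where(resistant, 0.3, 0.7)
    mgmt_methylated = pd.Series(
        rng.random(config.n_patients) < p_meth, index=pid, name="mgmt_methylated"
    )

    # --- expression: NB counts with marker / MGMT / subtype structure
    base = np.exp(rng.normal(4.5, 1.0, size=len(genes)))
    mu = np.tile(base[:, None], (1, config.n_patients))
    gindex = {g: i for i, g in enumerate(genes)}
    for g in MARKER_GENES:
        mu[gindex[g], resistant] *= 2.0**config.marker_log2fc
    # unmethylated promoter -> MGMT expressed (repair active, TMZ-resistant)
    mu[gindex["MGMT"], ~mgmt_methylated.values] *= 2.0**1.5
    for i, st in enumerate(SUBTYPES):
        rows = [gindex[g] for g in gene_sets[f"signature_{st}"]]
        cols = (subtype == st).values
        mu[np.ix_(rows, cols)] *= 2.0**config.subtype_log2fc
    counts = pd.DataFrame(
        _nb_sample(mu, config.dispersion, rng), index=gene_lengths.index, columns=pid
    )

    # --- CNA truth and log2 profiles
    cna_classes = pd.DataFrame(
        "neutral", index=pd.Index(CNA_GENES, name="gene"), columns=pid
    )
    p_triple = np.array(
        [config.concurrent_cna_rates[lab] for lab in labels], dtype=float
    )
    has_triple = rng.random(config.n_patients) < p_triple
    cna_classes.loc["PTEN", has_triple] = "loss"
    cna_classes.loc["EGFR", has_triple] = "amplification"
    cna_classes.loc["CDKN2A/B", has_triple] = "deletion"
    # sporadic background lesions, label-independent
    for g, cls, rate in (
        ("PDGFRA", "amplification", 0.12),
        ("CDK4", "amplification", 0.12),
        ("MDM2", "amplification", 0.08),
        ("PTEN", "deletion", 0.05),
        ("EGFR", "gain", 0.1),
    ):
        hit = (rng.random(config.n_patients) < rate) & (
            cna_classes.loc[g] == "neutral"
        ).values
        cna_classes.loc[g, hit] = cls
    centers = cna_classes.apply(lambda col: col.map(CLASS_CENTERS)).astype(float)
    cna_log2 = centers + rng.normal(
        0.0, config.cna_noise_sd, size=centers.shape
    ) if config.cna_noise_sd > 0 else centers
    concurrent = pd.Series(has_triple, index=pid, name="concurrent_cna")

    # --- somatic variants: label-enriched drivers plus filterable chaff
    var_rows = []
    enrich = {"NF1": (0.30, 0.10), "PTEN": (0.35, 0.20), "PIK3R1": (0.08, 0.20)}
    for g in DRIVER_SNV_GENES:
        p_res, p_sen = enrich.get(g, (0.15, 0.15))
        p_mut = np.where(resistant, p_res, p_sen)
        for s, hit in zip(ids, rng.random(config.n_patients) < p_mut):
            if hit:
                var_rows.append(
                    (s, g, rng.choice(["moderate", "high"], p=[0.7, 0.3]),
                     round(float(rng.uniform(0.1, 0.6)), 4), 0.0)
                )
        # chaff that the VAF / effect filters must remove
    for s in ids:
        for _ in range(int(rng.integers(0, 3))):
            kind = rng.choice(["synonymous", "low_vaf", "germline"])
            g = genes[int(rng.integers(0, len(genes)))]
            if kind == "synonymous":
                var_rows.append((s, g, "synonymous",
                                 round(float(rng.uniform(0.1, 0.6)), 4), 0.0))
            elif kind == "low_vaf":
                var_rows.append((s, g, "moderate",
                                 round(float(rng.uniform(0.0, 0.05)), 4), 0.0))
            else:
                var_rows.append((s, g, "moderate",
                                 round(float(rng.uniform(0.3, 0.6)), 4),
                                 round(float(rng.uniform(0.2, 0.5)), 4)))
    variants = pd.DataFrame(
        var_rows, columns=["sample_id", "gene", "effect_class", "vaf_tumor", "vaf_blood"]
    )

    # --- EGFRvIII skip reads: positives mostly among EGFR-amplified tumors
    p_viii = np.where(
        (cna_classes.loc["EGFR"] == "amplification").values, 0.4, 0.05
    )
    viii = rng.random(config.n_patients) < p_viii
    egfrviii_reads = pd.Series(
        np.where(viii, rng.poisson(8.0, config.n_patients), 0).astype(int),
        index=pid, name="egfrviii_skip_reads",
    )

    # --- survival: exponential PFS/OS, HR applied to resistant patients
    lam0 = math.log(2.0) / 10.0  # median sensitive PFS ~ 10 months
    rate = lam0 * np.where(resistant, config.survival_hr, 1.0)
    pfs = rng.exponential(1.0 / rate)
    os_ = pfs + rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        lam_c = lam0 * config.censor_rate / (1.0 - config.censor_rate)
        censor = rng.exponential(1.0 / lam_c, size=config.n_patients)
    else:
        censor = np.full(config.n_patients, np.inf)
    clinical = pd.DataFrame(
        {
            "age": rng.integers(29, 81, config.n_patients),
            "gender": rng.choice(["female", "male"], config.n_patients),
            "mgmt_methylated": mgmt_methylated.astype(int),
            "extent_of_resection": rng.choice(["GTR", "STR"], config.n_patients),
            "pfs_time": np.round(np.minimum(pfs, censor), 4),
            "pfs_event": (pfs <= censor).astype(int),
            "os_time": np.round(np.minimum(os_, censor), 4),
            "os_event": (os_ <= censor).astype(int),
            "sensitivity": labels,
        },
        index=pid,
    )

    bundle = CohortBundle(
        plates=plates,
        variants=variants,
        counts=counts,
        gene_lengths=gene_lengths,
        cna_log2=cna_log2,
        clinical=clinical,
        gene_sets=gene_sets,
        egfrviii_reads=egfrviii_reads,
    )
    truth = SyntheticTruth(
        labels=labels,
        gr50=gr50,
        subtype=subtype,
        cna_classes=cna_classes,
        marker_genes=MARKER_GENES,
        concurrent_cna=concurrent,
        mgmt_methylated=mgmt_methylated,
    )
    return bundle, truth


def build_feature_sources(
    bundle: CohortBundle,
    config: SimulationConfig,
    apply_missingness: bool = True,
) -> dict[str, pd.Series]:
    """Run the upstream rules over a bundle to produce classifier inputs.

    Expression features come from the normalised matrix, CNA indicators from
    the log2 profiles through the calling rules, SNV indicators from the
    filtered variant table, subtype indicators from ssGSEA assignment, and
    the EGFRvIII flag from the skip-read rule.  When ``apply_missingness``
    each feature independently loses a ``missing_rate`` fraction of entries
    at random (seeded off the config seed).
    """
    from .expression import normalize_expression
    from .genomic import (
        concurrent_cna_flag,
        detect_egfrviii,
        filter_somatic_variants,
        merge_cna_sources,
        CnaCall,
        SomaticVariantRecord,
    )
    from .subtyping import assign_subtype, score_gene_sets

    ids = bundle.clinical.index
    norm = normalize_expression(bundle.counts, bundle.gene_lengths)

    sources: dict[str, pd.Series] = {}
    for g in MARKER_GENES:
        sources[f"{g}_expression"] = norm.loc[g]
    sources["MGMT_expression"] = norm.loc["MGMT"]
    sources["MGMT_promoter_methylation"] = bundle.clinical["mgmt_methylated"].astype(
        float
    )
    sources["MGMT_fusion"] = pd.Series(0.0, index=ids)

    # CNA indicators through the calling + merge rules
    profiles = {}
    for s in ids:
        calls = [
            CnaCall(g, float(bundle.cna_log2.at[g, s]),
                    call_cna_class(float(bundle.cna_log2.at[g, s]), g, "WES"), "WES")
            for g in bundle.cna_log2.index
        ]
        profiles[s] = merge_cna_sources(s, {"WES": calls})
    amp = {"EGFR": "EGFR_amplification", "PDGFRA": "PDGFRA_amplification",
           "CDK4": "CDK4_amplification", "MDM2": "MDM2_amplification"}
    dele = {"PTEN": "PTEN_deletion", "CDKN2A/B": "CDKN2AB_deletion"}
    for g, feat in amp.items():
        sources[feat] = pd.Series(
            {s: float(profiles[s].cna_class(g) == "amplification") for s in ids}
        )
    for g, feat in dele.items():
        sources[feat] = pd.Series(
            {s: float(profiles[s].cna_class(g) in ("deletion", "loss")) for s in ids}
        )
    sources["concurrent_PTEN_EGFR_CDKN2AB"] = pd.Series(
        {s: float(bool(concurrent_cna_flag(profiles[s]))) for s in ids}
    )

    # SNV indicators from the filtered variant table
    records = [
        SomaticVariantRecord(*row)
        for row in bundle.variants.itertuples(index=False)
    ]
    kept = filter_somatic_variants(records)
    mutated = {(r.sample_id, r.gene) for r in kept}
    for g in DRIVER_SNV_GENES:
        if g == "NF2":
            continue
        sources[f"{g}_mutation"] = pd.Series(
            {s: float((s, g) in mutated) for s in ids}
        )

    sources["EGFRvIII"] = bundle.egfrviii_reads.map(
        lambda n: float(detect_egfrviii(int(n)))
    )

    scores = score_gene_sets(norm, bundle.gene_sets)
    assigned = assign_subtype(
        scores.rename(columns=lambda c: c.removeprefix("signature_"))
    ).assignment
    for st, feat in (
        ("classical", "subtype_CL"),
        ("proneural", "subtype_PN"),
        ("mesenchymal", "subtype_MES"),
    ):
        sources[feat] = (assigned == st).astype(float)

    if apply_missingness and config.missing_rate > 0:
        rng = np.random.default_rng(config.seed + 1)
        for feat, values in sources.items():
            mask = rng.random(len(values)) < config.missing_rate
            v = values.copy()
            v[mask] = np.nan
            sources[feat] = v
    return sources


def write_bundle(
    bundle: CohortBundle, truth: SyntheticTruth, out_dir: str | Path
) -> None:
    """Serialise a bundle as a directory of TSV files plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate_rows = []
    for p in bundle.plates:
        for c, v in zip(p.concentrations, p.viability):
            plate_rows.append((p.sample_id, c, v, "treated"))
        plate_rows.append((p.sample_id, np.nan, p.control_signal, "control"))
        plate_rows.append((p.sample_id, np.nan, p.t0_signal, "t0"))
    pd.DataFrame(
        plate_rows, columns=["sample_id", "concentration_uM", "signal", "well_role"]
    ).to_csv(out / "plates.tsv", sep="\t", index=False)
    bundle.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    bundle.counts.to_csv(out / "counts.tsv", sep="\t")
    bundle.gene_lengths.to_csv(out / "gene_lengths.tsv", sep="\t")
    bundle.cna_log2.to_csv(out / "cna_log2.tsv", sep="\t")
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t")
    bundle.egfrviii_reads.to_csv(out / "egfrviii_reads.tsv", sep="\t")
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, genes in bundle.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
    (out / "truth.json").write_text(truth.to_json())
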