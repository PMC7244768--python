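"""Synthetic cohorts, reads and outcomes with the assay's structure.

No patient-level data accompany the assay, so testing relies on a
generator that emulates what the chemistry and the disease biology
produce:

* a tumour expression *template* per B-NHL subtype, hand-authored from the
  qualitative marker signatures the panel was designed to capture (e.g.
  FL: germinal-centre programme, Tfh infiltrate and the I-epsilon sterile
  transcript; MCL: CCND1/CD5/BCL2-high with CD10/CD23 low; ABC: activated
  B-cell programme with IGHM+AICDA high but the I-mu sterile transcript
  low; PMBL: PDL1/PDL2/JAK2/CD30/CD23 high),
* dilution of the tumour signal by microenvironment components (T cells,
  Tfh cells, macrophages, cytotoxic cells) at a subtype-dependent tumour
  fraction,
* per-marker lognormal biological noise followed by multinomial molecular
  sampling at a lognormal per-sample depth (median 20,000 molecules),
* read-level structure: one read per PCR duplicate of each molecule
  (geometric multiplicity, mean 4), uniform substitution errors, and
  chimeric ligation artefacts,
* exponential survival times with per-covariate proportional hazards,
  independent exponential censoring and an administrative 60-month cap.

Every draw flows from a single seed, so cohorts, reads and outcomes are
fully reproducible.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import SUBTYPES, LabeledCohort
from .panel import PanelDefinition, default_panel, ligation_products
from .quantify import aggregate_dual_probes, normalize
from .readproc import ReadLayout, UmiCountMatrix
from .survival import CENSOR_HORIZON_MONTHS, apply_censoring_cap

MICROENV_COMPONENTS = ("T_CELL", "TFH", "MACROPHAGE", "CYTOTOXIC")

#: share of total molecules reserved for each mutation/virus locus
#: (reference probe background)
MUTATION_LOCUS_MASS = 0.002


@dataclass(frozen=True)
class SubtypeTemplate:
    """Expected tumour-cell marker abundances for one subtype."""

    label: str
    marker_means: pd.Series                  # over expression genes, sums to 1
    tumor_fraction_range: tuple[float, float] = (0.5, 0.9)
    microenvironment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        means = self.marker_means
        if (means < 0).any() or not np.isclose(means.sum(), 1.0):
            raise ValueError(f"{self.label}: marker_means must be a "
                             "distribution")
        lo, hi = self.tumor_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"{self.label}: bad tumor_fraction_range")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; defaults are the reference study conditions."""

    n_per_class: int = 40
    depth_median: float = 20_000.0     # molecules per sample
    depth_sigma: float = 0.35          # lognormal sigma of depth
    noise_scale: float = 1.0           # per-marker lognormal sigma
    seq_error_rate: float = 0.005      # substitutions per base
    chimera_rate: float = 0.01         # chimeric fraction of reads
    pcr_duplicate_mean: float = 4.0    # geometric mean reads per molecule
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.seq_error_rate <= 0.05):
            raise ValueError("seq_error_rate out of [0, 0.05]")
        if not (0 <= self.chimera_rate < 1):
            raise ValueError("chimera_rate out of [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.pcr_duplicate_mean < 1:
            raise ValueError("pcr_duplicate_mean must be >= 1")


def _profile(genes: list[str], base: dict[str, float],
             high: list[str] = (), low: list[str] = (),
             high_factor: float = 12.0, low_factor: float = 0.1) -> pd.Series:
    w = pd.Series({g: base.get(g, 1.0) for g in genes}, dtype=float)
    for g in high:
        w[g] = w[g] * high_factor
    for g in low:
        w[g] = w[g] * low_factor
    return w / w.sum()


def microenvironment_profiles(panel: PanelDefinition | None = None
                              ) -> dict[str, pd.Series]:
    """Expression profiles of the non-tumour components."""
    panel = panel or default_panel()
    genes = panel.expression_markers
    base = {g: 0.2 for g in genes}
    comp_genes = {
        "T_CELL": ["CD3E", "CD2", "CD4", "CD5", "CD28", "TRBC1", "GATA3",
                   "CCR4", "CTLA4", "IL2RA", "PTPRC"],
        "TFH": ["ICOS", "CD40LG", "CXCL13", "PDCD1", "CD4", "CD3E", "CD28"],
        "MACROPHAGE": ["CD68", "CD163", "PTPRC", "TNFSF13B", "IL10"],
        "CYTOTOXIC": ["CD8A", "GZMB", "PRF1", "EOMES", "TBX21", "CD3E",
                      "CD2"],
    }
    return {name: _profile(genes, base, high=gs, high_factor=60.0)
            for name, gs in comp_genes.items()}


def default_templates(panel: PanelDefinition | None = None
                      ) -> dict[str, SubtypeTemplate]:
    """Hand-authored subtype templates over the default panel's markers."""
    panel = panel or default_panel()
    genes = panel.expression_markers
    groups = {p.gene: p.group for p in panel.expression_probes}
    # tumour cells express the B-cell programme above the panel background
    base = {g: (3.0 if groups[g] in ("B_CELL", "IG_TRANSCRIPT",
                                     "DOUBLE_EXPRESSOR") else 0.3)
            for g in genes}

    spec = {
        "ABC": dict(
            high=["IRF4", "FOXP1", "LIMD1", "TNFRSF13B", "SH3BP5", "CCDC50",
                  "PIM1", "NFKBIA", "BATF", "IGHM", "AICDA", "BCL2"],
            low=["IMU_CMU", "MME", "LMO2", "MYBL1", "SERPINA9", "FCER2"],
            tf=(0.5, 0.9),
            me={"T_CELL": 0.4, "MACROPHAGE": 0.3, "CYTOTOXIC": 0.3}),
        "GCB": dict(
            high=["MME", "LMO2", "MYBL1", "NEK6", "S1PR2", "MAML3",
                  "SERPINA9", "LRMP", "ITPKB", "ASB13", "BCL6", "MKI67",
                  "IGAMMA_CGAMMA"],
            low=["IGHM", "IGHD", "IRF4", "FOXP1", "TNFRSF13B"],
            tf=(0.5, 0.9),
            me={"T_CELL": 0.4, "MACROPHAGE": 0.3, "CYTOTOXIC": 0.3}),
        "PMBL": dict(
            high=["CD274", "PDCD1LG2", "JAK2", "TNFRSF8", "FCER2", "CIITA",
                  "STAT6", "TRAF1", "REL", "NFKB2"],
            low=["BANK1", "CARD11", "TCL1A", "IGHM", "IGHD", "IGKC"],
            tf=(0.5, 0.9),
            me={"T_CELL": 0.5, "MACROPHAGE": 0.3, "CYTOTOXIC": 0.2}),
        "FL": dict(
            high=["MME", "LMO2", "MYBL1", "BCL6", "BCL2",
                  "IEPSILON_CEPSILON", "FCER2", "MEF2B"],
            low=["IGHM", "MKI67", "IRF4", "CCND1"],
            tf=(0.3, 0.6),
            me={"TFH": 0.45, "T_CELL": 0.45, "MACROPHAGE": 0.05,
                "CYTOTOXIC": 0.05}),
        "MCL": dict(
            high=["CCND1", "CD5", "BCL2", "TCL1A", "CCDC50", "CXCR5",
                  "IGHD", "IGHM", "IMU_CMU", "IGAMMA_CGAMMA", "SOX11"
                  ] if "SOX11" in genes else
                 ["CCND1", "CD5", "BCL2", "TCL1A", "CCDC50", "CXCR5",
                  "IGHD", "IGHM", "IMU_CMU", "IGAMMA_CGAMMA"],
            low=["MME", "FCER2", "BCL6", "LMO2"],
            tf=(0.4, 0.8),
            me={"T_CELL": 0.7, "MACROPHAGE": 0.2, "CYTOTOXIC": 0.1}),
        "SLL": dict(
            high=["CD5", "FCER2", "CD27", "JAK2", "IGHD", "IGHM", "IMU_CMU",
                  "IGAMMA_CGAMMA", "CCND2"],
            low=["MME", "SH3BP5", "MKI67", "CCND1"],
            tf=(0.5, 0.9),
            me={"T_CELL": 0.7, "MACROPHAGE": 0.2, "CYTOTOXIC": 0.1}),
        "MZL": dict(
            high=["SDC1", "IGHM", "IMU_CMU", "CD27", "KLF2", "NOTCH2"],
            low=["CD5", "MME", "FCER2", "MKI67", "CCND1", "AICDA"],
            tf=(0.4, 0.8),
            me={"T_CELL": 0.6, "MACROPHAGE": 0.25, "CYTOTOXIC": 0.15}),
    }
    out = {}
    for label, s in spec.items():
        out[label] = SubtypeTemplate(
            label=label,
            marker_means=_profile(genes, base, s["high"], s["low"]),
            tumor_fraction_range=s["tf"],
            microenvironment=s["me"])
    return out


@dataclass
class SimulatedCohort:
    """Counts, labels and generator ground truth for one synthetic cohort."""

    counts: UmiCountMatrix
    labels: pd.Series
    truth: pd.DataFrame    # tumor_fraction, depth per sample

    def to_labeled_cohort(self, panel: PanelDefinition) -> LabeledCohort:
        expr = aggregate_dual_probes(
            normalize(self.counts, panel, include_non_interpretable=True),
            panel)
        return LabeledCohort(expr, self.labels.loc[expr.index])


def _expected_probe_probs(mean_genes: pd.Series,
                          panel: PanelDefinition) -> pd.Series:
    """Distribute gene-level mass over probe pairs and mutation loci."""
    per_gene_pairs: dict[str, list[str]] = {}
    for p in panel.expression_probes:
        per_gene_pairs.setdefault(p.gene, []).append(p.marker_id)
    n_loci = len(panel.mutation_loci)
    expr_mass = 1.0 - MUTATION_LOCUS_MASS * n_loci
    probs = pd.Series(0.0, index=panel.marker_ids)
    for gene, pairs in per_gene_pairs.items():
        share = expr_mass * mean_genes.get(gene, 0.0) / len(pairs)
        for m in pairs:
            probs[m] = share
    for locus in panel.mutation_loci:
        probs[f"{locus}_2"] = MUTATION_LOCUS_MASS  # reference probe only
    return probs / probs.sum()


def expected_expression(template: SubtypeTemplate,
                        panel: PanelDefinition,
                        tumor_fraction: float | None = None) -> pd.Series:
    """Noise-free gene-level expression of a template (prototype profile)."""
    me = microenvironment_profiles(panel)
    lo, hi = template.tumor_fraction_range
    tf = tumor_fraction if tumor_fraction is not None else (lo + hi) / 2
    mix = tf * template.marker_means
    weights = template.microenvironment or {"T_CELL": 1.0}
    wsum = sum(weights.values())
    for name, w in weights.items():
        mix = mix + (1 - tf) * (w / wsum) * me[name]
    mix = mix / mix.sum()
    return np.log2(1.0 + 10_000 * mix)


def simulate_cohort(config: SimConfig | None = None,
                    templates: dict[str, SubtypeTemplate] | None = None,
                    panel: PanelDefinition | None = None) -> SimulatedCohort:
    """Draw a labelled cohort of probe-level molecule counts.

    Per sample: tumour fraction ~ U(template range); tumour and
    microenvironment profiles are mixed, perturbed marker-wise by
    lognormal(0, noise_scale) noise, renormalised, and molecule counts are
    drawn multinomially at a lognormal depth.
    """
    config = config or SimConfig()
    panel = panel or default_panel()
    templates = templates or default_templates(panel)
    rng = np.random.default_rng(config.seed)
    me = microenvironment_profiles(panel)
    rows, labels, truth = [], [], []
    sample_ids = []
    for label in [s for s in SUBTYPES if s in templates]:
        tmpl = templates[label]
        for i in range(config.n_per_class):
            sid = f"{label}_{i:03d}"
            lo, hi = tmpl.tumor_fraction_range
            tf = rng.uniform(lo, hi)
            mix = tf * tmpl.marker_means
            weights = tmpl.microenvironment or {"T_CELL": 1.0}
            wsum = sum(weights.values())
            for name, w in weights.items():
                mix = mix + (1 - tf) * (w / wsum) * me[name]
            noisy = mix * np.exp(rng.normal(0.0, config.noise_scale,
                                            len(mix)))
            noisy = noisy / noisy.sum()
            probs = _expected_probe_probs(noisy, panel)
            depth = int(np.round(config.depth_median
                                 * np.exp(rng.normal(0.0,
                                                     config.depth_sigma))))
            counts = rng.multinomial(depth, probs.to_numpy())
            rows.append(counts)
            labels.append(label)
            truth.append({"tumor_fraction": tf, "depth": depth})
            sample_ids.append(sid)
    counts_df = pd.DataFrame(
        np.asarray(rows, dtype=int) if rows else
        np.empty((0, len(panel.marker_ids)), dtype=int),
        index=sample_ids, columns=panel.marker_ids)
    stats = pd.DataFrame(0, index=sample_ids,
                         columns=["no_match", "chimeric", "below_quality"])
    return SimulatedCohort(
        counts=UmiCountMatrix(counts=counts_df, discard_stats=stats),
        labels=pd.Series(labels, index=sample_ids, name="subtype"),
        truth=pd.DataFrame(truth, index=sample_ids))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """n distinct random UMIs."""
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            out.add("".join("ACGT"[b] for b in row))
    return sorted(out)[:n] if len(out) == n else list(out)[:n]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_fastq(counts_row: pd.Series, panel: PanelDefinition,
                   layout: ReadLayout | None = None,
                   config: SimConfig | None = None,
                   path: str = "sample.fastq",
                   seed: int | None = None) -> int:
    """Write FASTQ reads realising a molecule-count vector; returns #reads.

    Each molecule gets a distinct UMI per marker and Geometric(1/mean) >= 1
    PCR-duplicate reads; bases are substituted uniformly at the configured
    error rate and chimeric reads (left half of one probe ligated to the
    right half of another, fresh UMI) are injected at the chimera rate.
    Read order is shuffled.  At zero error and chimera rate,
    ``count_fastq`` recovers the input counts exactly.
    """
    config = config or SimConfig()
    layout = layout or ReadLayout(umi_length=panel.umi_length,
                                  insert_offset=panel.umi_length)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    products = ligation_products(panel)
    reads: list[str] = []
    p_geom = 1.0 / config.pcr_duplicate_mean
    for marker_id, n in counts_row.items():
        n = int(n)
        if n == 0:
            continue
        product = products[marker_id]
        umis = _random_umis(n, layout.umi_length, rng)
        dup = rng.geometric(p_geom, size=n)
        for umi, k in zip(umis, dup):
            base_read = umi + product
            for _ in range(int(k)):
                reads.append(_mutate(base_read, config.seq_error_rate, rng))
    if config.chimera_rate > 0 and reads:
        n_chim = rng.binomial(
            len(reads), config.chimera_rate / (1 - config.chimera_rate))
        probes = panel.probes
        for _ in range(n_chim):
            a, b = rng.choice(len(probes), size=2, replace=False)
            umi = "".join("ACGT"[i] for i in rng.integers(0, 4,
                                                          layout.umi_length))
            read = umi + probes[a].left_seq + probes[b].right_seq
            reads.append(_mutate(read, config.seq_error_rate, rng))
    rng.shuffle(reads)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def simulate_survival(covariates: pd.DataFrame | pd.Series,
                      effects: dict[str, float] | None = None,
                      baseline_median_months: float = 36.0,
                      censor_rate: float = 0.006,
                      horizon: float = CENSOR_HORIZON_MONTHS,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential event times under proportional hazards per covariate.

    ``covariates`` holds boolean flags per sample (a Series is treated as
    ``double_expressor``); ``effects`` maps covariate name to hazard ratio
    (default ``{"double_expressor": 2.0}``).  Censoring is independent
    exponential at ``censor_rate`` per month plus the administrative cap.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame("double_expressor")
    effects = effects or {"double_expressor": 2.0}
    unknown = set(effects) - set(covariates.columns)
    if unknown:
        raise ValueError(f"effects for unknown covariates: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lam0 = np.log(2.0) / baseline_median_months
    log_hr = np.zeros(len(covariates))
    for name, hr in effects.items():
        log_hr += np.log(hr) * covariates[name].astype(float).to_numpy()
    lam = lam0 * np.exp(log_hr)
    event_t = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=len(lam))
    else:
        censor_t = np.full(len(lam), np.inf)
    time = np.minimum(event_t, censor_t)
    event = event_t <= censor_t
    records = pd.DataFrame({"time": time, "event": event},
                           index=covariates.index)
    records = pd.concat([records, covariates.astype(bool)], axis=1)
    return apply_censoring_cap(records, horizon)
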