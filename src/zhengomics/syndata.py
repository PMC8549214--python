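"""Synthetic cohort, omics and knowledge-base generator with planted truth.

Everything downstream of sample acquisition is exercisable on data from
this module: a serum proteomics table (log-normal intensities spanning
about six decades, standard-sample replicates with a calibrated technical
CV, abundance-dependent dropout), untargeted and targeted metabolomics
tables with ten chemical categories at study-like proportions, and a toy
knowledge base (six herbal formulae with the study's herb counts, compound
records straddling the OB/DL activity thresholds, disease gene/variant
sets, ATC-coded drug records, a PPI network and a metabolite-gene
association network).

Planted structure: differential proteins/metabolites are shifted by
``effect_log2fc`` on the log2 scale in their syndrome's samples;
per-syndrome signature-target cores are injected into every formula of the
syndrome through guaranteed-active carrier compounds; drug target sets are
drawn so that each ATC category preferentially hits one signature
partition; two syndrome-specific pathways collect planted DPs and DMs so
that enrichment signal survives into the integrated view.  A
:class:`GroundTruth` sidecar records all planted identities so recall/FDR
can be measured without re-deriving them.

The same seed always reproduces byte-identical outputs; independent
substreams keep the three generators decoupled from call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from zhengomics.tables import OmicsTable, STANDARD_GROUP
from zhengomics import io as zio
from zhengomics.netpharm import CompoundRecord, FormulaDef, DiseaseRecord, DrugRecord

LN2 = np.log(2.0)

#: chemical-category mix of differential metabolites (study-like shares)
MET_CATEGORIES = {
    "glycerophospholipids": 0.253,
    "fatty_acyls": 0.233,
    "amino_acids": 0.144,
    "sphingolipids": 0.080,
    "amines": 0.060,
    "organic_acids": 0.060,
    "benzenoids": 0.050,
    "carbohydrates": 0.045,
    "nucleosides": 0.040,
    "sterol_lipids": 0.035,
}

#: herbs per formula, in code order F1-1..F2-3
FORMULA_HERB_COUNTS = (7, 5, 5, 2, 11, 3)
FORMULA_CODES = ("F1-1", "F1-2", "F1-3", "F2-1", "F2-2", "F2-3")
FORMULA_SYNDROMES = ("CCQS", "CCQS", "CCQS", "QSBS", "QSBS", "QSBS")
N_DISTINCT_HERBS = 26


@dataclass
class SynConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    seed: int = 0
    # cohort
    n_ccqs: int = 44
    n_qsbs: int = 37
    n_hc: int = 30
    n_standard: int = 11
    # proteomics
    n_proteins_identified: int = 470
    n_proteins_quantified: int = 388
    planted_dp_counts: tuple = (17, 16, 7)        # CCQS-only, QSBS-only, shared
    # metabolomics
    n_met_untargeted: int = 1000
    n_met_targeted: int = 306
    planted_dm_counts: tuple = (90, 115, 110)     # untargeted
    planted_dm_counts_targeted: tuple = (28, 35, 34)
    # signal and noise
    effect_log2fc: float = 0.5
    biological_sd_log2: float = 0.2
    cv_standard: float = 0.05
    missing_rate: float = 0.01
    # knowledge base
    kb_n_genes: int = 800
    kb_n_variants: int = 600
    kb_core_common: int = 18
    kb_core_ccqs: int = 12
    kb_core_qsbs: int = 10
    kb_n_pathways: int = 24
    kb_n_diseases: int = 40
    kb_n_related_diseases: int = 15
    kb_sig_overlap: float = 1.0   # fraction of the core injected into every formula

    def __post_init__(self) -> None:
        counts = [
            self.n_ccqs, self.n_qsbs, self.n_hc, self.n_standard,
            self.n_proteins_identified, self.n_proteins_quantified,
            self.n_met_untargeted, self.n_met_targeted,
            self.kb_n_genes, self.kb_n_variants, self.kb_n_pathways,
            self.kb_n_diseases,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if sum(self.planted_dp_counts) > self.n_proteins_quantified:
            raise ValueError("planted DP counts exceed quantified protein count")
        if sum(self.planted_dm_counts) > self.n_met_untargeted:
            raise ValueError("planted DM counts exceed untargeted feature count")
        if sum(self.planted_dm_counts_targeted) > self.n_met_targeted:
            raise ValueError("planted DM counts exceed targeted feature count")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.kb_sig_overlap <= 1):
            raise ValueError("kb_sig_overlap must be in [0, 1]")
        if self.n_proteins_identified < self.n_proteins_quantified:
            raise ValueError("identified proteins cannot be fewer than quantified")
        if self.n_proteins_identified > self.kb_n_genes:
            raise ValueError("protein count exceeds the gene universe")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("planted_dp_counts", "planted_dm_counts", "planted_dm_counts_targeted"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("planted_dp_counts", "planted_dm_counts", "planted_dm_counts_targeted"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted identities of one synthetic run (sidecar for evaluation)."""

    dp: dict = field(default_factory=dict)            # syndrome -> {gene: direction}
    dp_shared: set = field(default_factory=set)
    dm_untargeted: dict = field(default_factory=dict)  # syndrome -> {met: direction}
    dm_shared_untargeted: set = field(default_factory=set)
    dm_targeted: dict = field(default_factory=dict)
    dm_shared_targeted: set = field(default_factory=set)
    dm_categories: dict = field(default_factory=dict)  # met -> category
    formula_targets: dict = field(default_factory=dict)  # code -> set
    signature_core: dict = field(default_factory=dict)   # common/CCQS/QSBS -> set
    related_diseases: set = field(default_factory=set)
    panel_markers: dict = field(default_factory=dict)    # syndrome -> {kind: [ids]}
    planted_pathways: dict = field(default_factory=dict)  # syndrome/common -> term

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in ("dp", "dm_untargeted", "dm_targeted", "dm_categories",
                     "formula_targets", "signature_core", "panel_markers",
                     "planted_pathways"):
            getattr(self, name).update(getattr(other, name))
        self.dp_shared |= other.dp_shared
        self.dm_shared_untargeted |= other.dm_shared_untargeted
        self.dm_shared_targeted |= other.dm_shared_targeted
        self.related_diseases |= other.related_diseases
        return self

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for syn, d in self.dp.items():
            for gene, direction in sorted(d.items()):
                shared = gene in self.dp_shared
                rows.append(("dp", syn, gene, direction, shared))
        for syn, d in self.dm_untargeted.items():
            for met, direction in sorted(d.items()):
                rows.append(("dm_untargeted", syn, met, direction, met in self.dm_shared_untargeted))
        for syn, d in self.dm_targeted.items():
            for met, direction in sorted(d.items()):
                rows.append(("dm_targeted", syn, met, direction, met in self.dm_shared_targeted))
        for part, genes in self.signature_core.items():
            for g in sorted(genes):
                rows.append(("signature_core", part, g, "", False))
        for dz in sorted(self.related_diseases):
            rows.append(("related_disease", "", dz, "", False))
        pd.DataFrame(rows, columns=["kind", "group", "id", "direction", "shared"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# shared deterministic layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    genes_identified: list
    genes_quantified: list
    dp: dict
    dp_shared: set
    dm_unt: dict
    dm_shared_unt: set
    dm_tgt: dict
    dm_shared_tgt: set
    met_ids_unt: list
    met_ids_tgt: list
    met_categories: dict
    core_common: set
    core_ccqs: set
    core_qsbs: set
    panel_markers: dict


def _split_planted(rng, pool, counts):
    """Draw (a_only, b_only, shared) disjoint id lists from a pool."""
    total = sum(counts)
    chosen = list(rng.choice(pool, size=total, replace=False))
    a = chosen[: counts[0]]
    b = chosen[counts[0]: counts[0] + counts[1]]
    shared = chosen[counts[0] + counts[1]:]
    return a, b, shared


def _with_directions(rng, ids_specific_a, ids_specific_b, shared):
    """Per-syndrome {id: direction} maps; shared features shift the same way."""
    dir_a = {i: str(rng.choice(["up", "down"])) for i in ids_specific_a}
    dir_b = {i: str(rng.choice(["up", "down"])) for i in ids_specific_b}
    dir_shared = {i: str(rng.choice(["up", "down"])) for i in shared}
    a = {**dir_a, **dir_shared}
    b = {**dir_b, **dir_shared}
    return a, b


def _layout(cfg: SynConfig) -> _Layout:
    """Planted identities shared between the three generators.

    Derived from a dedicated substream so that gen_proteomics,
    gen_metabolomics and gen_knowledgebase agree on identities regardless
    of which are called, in which order.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    genes = [f"G{i:04d}" for i in range(1, cfg.kb_n_genes + 1)]
    genes_identified = sorted(rng.choice(genes, size=cfg.n_proteins_identified, replace=False))
    genes_quantified = sorted(rng.choice(genes_identified, size=cfg.n_proteins_quantified,
                                         replace=False))

    dp_a, dp_b, dp_shared = _split_planted(rng, genes_quantified, cfg.planted_dp_counts)
    dp_ccqs, dp_qsbs = _with_directions(rng, dp_a, dp_b, dp_shared)

    met_unt = [f"M{i:04d}" for i in range(1, cfg.n_met_untargeted + 1)]
    met_tgt = [f"TM{i:04d}" for i in range(1, cfg.n_met_targeted + 1)]
    dm_a, dm_b, dm_sh = _split_planted(rng, met_unt, cfg.planted_dm_counts)
    dm_unt_ccqs, dm_unt_qsbs = _with_directions(rng, dm_a, dm_b, dm_sh)
    dmt_a, dmt_b, dmt_sh = _split_planted(rng, met_tgt, cfg.planted_dm_counts_targeted)
    dm_tgt_ccqs, dm_tgt_qsbs = _with_directions(rng, dmt_a, dmt_b, dmt_sh)

    cats = list(MET_CATEGORIES)
    probs = np.array(list(MET_CATEGORIES.values()))
    met_categories = {
        m: cats[i]
        for m, i in zip(met_unt + met_tgt,
                        rng.choice(len(cats), size=len(met_unt) + len(met_tgt), p=probs))
    }

    non_protein_genes = sorted(set(genes) - set(genes_identified))
    core_pool = list(rng.permutation(non_protein_genes))
    n_cc = cfg.kb_core_common
    core_common = set(core_pool[:n_cc])
    core_ccqs = set(core_pool[n_cc: n_cc + cfg.kb_core_ccqs])
    core_qsbs = set(core_pool[n_cc + cfg.kb_core_ccqs:
                              n_cc + cfg.kb_core_ccqs + cfg.kb_core_qsbs])

    panel = {
        "CCQS": {
            "proteins": sorted(rng.choice(dp_a, size=min(4, len(dp_a)), replace=False)),
            "metabolites": sorted(rng.choice(dm_a, size=min(4, len(dm_a)), replace=False)),
        },
        "QSBS": {
            "proteins": sorted(rng.choice(dp_b, size=min(4, len(dp_b)), replace=False)),
            "metabolites": sorted(rng.choice(dm_b, size=min(4, len(dm_b)), replace=False)),
        },
    }
    return _Layout(
        genes_identified, genes_quantified,
        {"CCQS": dp_ccqs, "QSBS": dp_qsbs}, set(dp_shared),
        {"CCQS": dm_unt_ccqs, "QSBS": dm_unt_qsbs}, set(dm_sh),
        {"CCQS": dm_tgt_ccqs, "QSBS": dm_tgt_qsbs}, set(dmt_sh),
        met_unt, met_tgt, met_categories,
        core_common, core_ccqs, core_qsbs, panel,
    )


def _sample_ids(cfg: SynConfig, with_standards: bool) -> tuple[list, pd.Series]:
    ids, groups = [], []
    for group, n in (("CCQS", cfg.n_ccqs), ("QSBS", cfg.n_qsbs), ("HC", cfg.n_hc)):
        for i in range(1, n + 1):
            ids.append(f"{group}_{i:02d}")
            groups.append(group)
    if with_standards:
        for i in range(1, cfg.n_standard + 1):
            ids.append(f"STD_{i:02d}")
            groups.append(STANDARD_GROUP)
    return ids, pd.Series(groups, index=ids)


def _apply_effects(log2: np.ndarray, feature_ids, groups: pd.Series,
                   planted: dict, effect: float) -> None:
    """Shift planted features by +/- effect in their syndrome's samples (in place)."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    cols = {syn: np.array([groups.iloc[j] == syn for j in range(len(groups))])
            for syn in planted}
    for syn, fdict in planted.items():
        for feat, direction in fdict.items():
            sign = 1.0 if direction == "up" else -1.0
            log2[idx[feat], cols[syn]] += sign * effect


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def gen_proteomics(cfg: SynConfig) -> tuple[OmicsTable, GroundTruth]:
    """Serum proteomics table: cohort + standard replicates, MNAR dropout.

    Quantified features draw baseline log2 abundances uniformly over about
    six decades; the identified-but-not-quantified remainder sits below
    them with heavy dropout.  Planted DPs (drawn from the upper 70% of the
    abundance range so they survive imputation) shift by
    ``effect_log2fc``.  Standard samples carry multiplicative log-normal
    technical noise calibrated to ``cv_standard`` and no dropout.
    """
    lay = _layout(cfg)
    rng = np.random.default_rng([cfg.seed % (2**31), 1])
    sample_ids, groups = _sample_ids(cfg, with_standards=True)
    n_samples = len(sample_ids)

    quant = lay.genes_quantified
    extra = sorted(set(lay.genes_identified) - set(quant))
    features = quant + extra
    n_quant = len(quant)

    lo, hi = 12.0, 31.0                      # ~ 6 orders of magnitude in log2
    base = np.empty(len(features))
    base[:n_quant] = rng.uniform(lo, hi, size=n_quant)
    base[n_quant:] = rng.uniform(8.0, lo, size=len(extra))
    # planted features must be well quantified: remap them into the upper 70%
    planted_all = set(lay.dp["CCQS"]) | set(lay.dp["QSBS"])
    cut = lo + 0.3 * (hi - lo)
    for i, f in enumerate(features):
        if f in planted_all and base[i] < cut:
            base[i] = rng.uniform(cut, hi)

    bio_sd = cfg.biological_sd_log2
    tech_sd = np.sqrt(np.log1p(cfg.cv_standard**2)) / LN2   # log2 sd giving CV ~= cv_standard
    is_std = (groups == STANDARD_GROUP).to_numpy()
    noise_sd = np.where(is_std, tech_sd, bio_sd)
    log2 = base[:, None] + rng.normal(0.0, 1.0, size=(len(features), n_samples)) * noise_sd

    _apply_effects(log2, features, groups, lay.dp, cfg.effect_log2fc)

    # abundance-dependent left-censoring: each cell drops out with a
    # logistic probability in its own log-intensity, so missing entries are
    # the low draws and half-min imputation lands near the censored truth
    from scipy.special import expit
    from scipy.stats import norm

    # one global soft detection floor: each cell drops out with logistic
    # probability in its own log2 intensity, so missingness concentrates in
    # low-abundance features and imputation lands near the censored truth
    scale = 1.5                                              # floor softness (log2 units)
    floor_lo, floor_hi = lo - 20.0, hi
    for _ in range(60):                                      # calibrate floor to missing_rate
        mid = 0.5 * (floor_lo + floor_hi)
        if expit((mid - base[:n_quant]) / scale).mean() < cfg.missing_rate:
            floor_lo = mid
        else:
            floor_hi = mid
    floor = 0.5 * (floor_lo + floor_hi)
    p_cell = expit((floor - log2[:n_quant]) / scale)
    mask = np.zeros((len(features), n_samples), dtype=bool)
    mask[:n_quant] = (rng.random((n_quant, n_samples)) < p_cell) & ~is_std[None, :]
    # identified-only proteins sit near/below the floor: heavy per-feature
    # censoring keeps them out of the reliably quantified tier
    eff_sd = np.sqrt(bio_sd**2 + (np.pi / np.sqrt(3) * 0.05) ** 2)
    censor_extra = base[n_quant:] + eff_sd * norm.ppf(0.8)
    p_cell_extra = expit((censor_extra[:, None] - log2[n_quant:]) / 0.05)
    mask[n_quant:] = rng.random((len(extra), n_samples)) < p_cell_extra
    # never lose a feature entirely
    all_missing = mask.all(axis=1)
    mask[all_missing, 0] = False

    values = np.power(2.0, log2)
    values[mask] = np.nan
    table = OmicsTable(pd.DataFrame(values, index=features, columns=sample_ids), groups)
    gt = GroundTruth(dp=lay.dp, dp_shared=lay.dp_shared, panel_markers=lay.panel_markers)
    return table, gt


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------

def gen_metabolomics(cfg: SynConfig) -> tuple[OmicsTable, OmicsTable, GroundTruth]:
    """Untargeted (peak-area) and targeted (concentration) tables.

    Features carry one of ten chemical categories at study-like
    proportions; planted DMs shift by ``effect_log2fc`` in their
    syndrome's samples.  No dropout: metabolomics matrices arrive complete
    after upstream peak processing.
    """
    lay = _layout(cfg)
    rng = np.random.default_rng([cfg.seed % (2**31), 2])
    sample_ids, groups = _sample_ids(cfg, with_standards=False)
    n_samples = len(sample_ids)

    def build(met_ids, base_lo, base_hi, planted):
        base = rng.uniform(base_lo, base_hi, size=len(met_ids))
        log2 = base[:, None] + rng.normal(0.0, cfg.biological_sd_log2,
                                          size=(len(met_ids), n_samples))
        _apply_effects(log2, met_ids, groups, planted, cfg.effect_log2fc)
        meta = pd.DataFrame({"category": [lay.met_categories[m] for m in met_ids]},
                            index=met_ids)
        return OmicsTable(pd.DataFrame(np.power(2.0, log2), index=met_ids,
                                       columns=sample_ids), groups, meta)

    unt = build(lay.met_ids_unt, 14.0, 28.0, lay.dm_unt)    # peak areas
    tgt = build(lay.met_ids_tgt, -2.0, 8.0, lay.dm_tgt)     # concentrations (uM scale)

    gt = GroundTruth(
        dm_untargeted=lay.dm_unt, dm_shared_untargeted=lay.dm_shared_unt,
        dm_targeted=lay.dm_tgt, dm_shared_targeted=lay.dm_shared_tgt,
        dm_categories=lay.met_categories, panel_markers=lay.panel_markers,
    )
    return unt, tgt, gt


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeBase:
    formulae: list
    compounds: list
    gene_universe: set
    met_universe: set
    pathways_genes: dict
    pathways_mets: dict
    pathways_joint: dict
    chd: DiseaseRecord
    diseases: list
    drugs: list
    ppi: nx.Graph
    metgene: nx.Graph


def _make_formulae(rng) -> list:
    herbs_all = [f"H{i:02d}" for i in range(1, N_DISTINCT_HERBS + 1)]
    formulae, used = [], []
    next_new = 0
    for code, syn, count in zip(FORMULA_CODES, FORMULA_SYNDROMES, FORMULA_HERB_COUNTS):
        herbs = []
        for _ in range(count):
            if next_new < N_DISTINCT_HERBS:
                herbs.append(herbs_all[next_new])
                next_new += 1
            else:  # reuse an existing herb not already in this formula
                pool = [h for h in used if h not in herbs]
                herbs.append(pool[rng.integers(len(pool))])
        used.extend(h for h in herbs if h not in used)
        formulae.append(FormulaDef(code, tuple(herbs), syn))
    return formulae


def gen_knowledgebase(cfg: SynConfig) -> tuple[KnowledgeBase, GroundTruth]:
    """Toy formula/compound/target/disease/drug/network knowledge base.

    Six formulae with the fixed herb counts (7, 5, 5, 2, 11, 3) over 26
    distinct herbs.  Each herb carries 12-24 compounds from the three
    source kinds with OB/DL (or grading) attributes straddling the
    activity thresholds.  A per-syndrome signature core is injected into
    every formula of the syndrome through a guaranteed-active Q-marker
    carrier compound, so the three-way target intersection provably
    contains the core.  Disease records are built so that exactly
    ``kb_n_related_diseases`` candidates exceed both Jaccard thresholds
    against the CHD query.  Drug target sets tie each ATC category to one
    signature partition (C -> common, A10 -> CCQS-specific, A08/B01 ->
    QSBS-specific).
    """
    lay = _layout(cfg)
    rng = np.random.default_rng([cfg.seed % (2**31), 3])
    genes = sorted({f"G{i:04d}" for i in range(1, cfg.kb_n_genes + 1)})
    formulae = _make_formulae(rng)

    core = {"CCQS": lay.core_common | lay.core_ccqs,
            "QSBS": lay.core_common | lay.core_qsbs}
    all_cores = lay.core_common | lay.core_ccqs | lay.core_qsbs
    random_target_pool = sorted(set(genes) - all_cores)

    compounds: list[CompoundRecord] = []
    cid = 0
    for formula in formulae:
        for herb in formula.herbs:
            if any(c.herb_id == herb for c in compounds):
                continue  # shared herb already populated
            n_comp = int(rng.integers(12, 25))
            for _ in range(n_comp):
                cid += 1
                source = ["tcmsp", "etcm", "qmarker"][
                    rng.choice(3, p=[0.5, 0.3, 0.2])
                ]
                if rng.random() < 0.75:
                    k = int(rng.integers(3, 13))
                    targets = frozenset(rng.choice(random_target_pool, size=k, replace=False))
                else:
                    targets = frozenset()
                if source == "tcmsp":
                    rec = CompoundRecord(f"C{cid:04d}", herb, "tcmsp",
                                         ob=float(np.round(rng.uniform(5, 70), 2)),
                                         dl=float(np.round(rng.uniform(0.02, 0.7), 3)),
                                         targets=targets)
                elif source == "etcm":
                    grading = ["good", "moderate", "weak", "none"][
                        rng.choice(4, p=[0.3, 0.25, 0.25, 0.2])
                    ]
                    rec = CompoundRecord(f"C{cid:04d}", herb, "etcm",
                                         grading=grading, targets=targets)
                else:
                    rec = CompoundRecord(f"C{cid:04d}", herb, "qmarker", targets=targets)
                compounds.append(rec)
    # core carrier: one always-active Q-marker per formula holding the core
    for formula in formulae:
        cid += 1
        full = sorted(core[formula.syndrome])
        n_take = int(round(cfg.kb_sig_overlap * len(full)))
        carried = frozenset(full[:n_take])
        compounds.append(CompoundRecord(f"C{cid:04d}", formula.herbs[0], "qmarker",
                                        targets=carried))

    # ground-truth per-formula target sets via generation-time bookkeeping
    active_by_herb: dict[str, list] = {}
    for rec in compounds:
        active = (
            (rec.source == "tcmsp" and rec.ob is not None and rec.dl is not None
             and rec.ob >= 30 and rec.dl >= 0.18)
            or (rec.source == "etcm" and rec.grading in {"good", "moderate"})
            or rec.source == "qmarker"
        )
        if active:
            active_by_herb.setdefault(rec.herb_id, []).append(rec)
    gt_formula_targets = {}
    for formula in formulae:
        t: set = set()
        for herb in formula.herbs:
            for rec in active_by_herb.get(herb, []):
                t |= set(rec.targets)
        gt_formula_targets[formula.code] = t

    # pathways: joint gene+metabolite sets; two carry the planted signal
    mets = lay.met_ids_unt
    pathways_genes, pathways_mets = {}, {}
    for i in range(1, cfg.kb_n_pathways + 1):
        term = f"PW{i:02d}"
        pathways_genes[term] = set(rng.choice(genes, size=int(rng.integers(8, 26)),
                                              replace=False))
        pathways_mets[term] = set(rng.choice(mets, size=int(rng.integers(4, 13)),
                                             replace=False))
    planted_pw = {}
    for syn, term in (("CCQS", "PW_CCQS"), ("QSBS", "PW_QSBS")):
        dp_specific = sorted(set(lay.dp[syn]) - lay.dp_shared)
        dm_specific = sorted(set(lay.dm_unt[syn]) - lay.dm_shared_unt)
        pathways_genes[term] = set(rng.choice(dp_specific, size=min(12, len(dp_specific)),
                                              replace=False)) | set(
            rng.choice(genes, size=6, replace=False))
        pathways_mets[term] = set(rng.choice(dm_specific, size=min(12, len(dm_specific)),
                                             replace=False))
        planted_pw[syn] = term
    pathways_genes["PW_COMMON"] = set(lay.dp_shared) | set(rng.choice(genes, size=5,
                                                                      replace=False))
    pathways_mets["PW_COMMON"] = set(
        rng.choice(sorted(lay.dm_shared_unt), size=min(12, len(lay.dm_shared_unt)),
                   replace=False))
    planted_pw["common"] = "PW_COMMON"
    pathways_joint = {t: pathways_genes[t] | pathways_mets[t] for t in pathways_genes}

    # diseases: CHD query + related/unrelated candidates
    variants = [f"V{i:04d}" for i in range(1, cfg.kb_n_variants + 1)]
    chd_genes = set(rng.choice(genes, size=120, replace=False))
    chd_vars = set(rng.choice(variants, size=80, replace=False))
    other_genes = sorted(set(genes) - chd_genes)
    other_vars = sorted(set(variants) - chd_vars)
    diseases, related = [], set()
    for i in range(1, cfg.kb_n_diseases + 1):
        did = f"DIS{i:02d}"
        if i <= cfg.kb_n_related_diseases:
            g = set(rng.choice(sorted(chd_genes), size=int(rng.integers(50, 91)),
                               replace=False))
            g |= set(rng.choice(other_genes, size=int(rng.integers(20, 51)), replace=False))
            # comorbidity coupling: related diseases recruit planted DP genes
            dp_pool = sorted(set(lay.dp["CCQS"]) | set(lay.dp["QSBS"]))
            g |= set(rng.choice(dp_pool, size=int(rng.integers(4, 9)), replace=False))
            v = set(rng.choice(sorted(chd_vars), size=int(rng.integers(15, 31)),
                               replace=False))
            v |= set(rng.choice(other_vars, size=int(rng.integers(20, 61)), replace=False))
            related.add(did)
        else:
            g = set(rng.choice(sorted(chd_genes), size=int(rng.integers(0, 12)),
                               replace=False))
            g |= set(rng.choice(other_genes, size=int(rng.integers(60, 120)), replace=False))
            v = set(rng.choice(other_vars, size=int(rng.integers(30, 80)), replace=False))
        diseases.append(DiseaseRecord(did, frozenset(g), frozenset(v)))
    chd = DiseaseRecord("CHD", frozenset(chd_genes), frozenset(chd_vars))

    # drugs: ATC category <-> signature partition coupling
    drug_specs = [("C", 14, sorted(lay.core_common)),
                  ("A10", 8, sorted(lay.core_ccqs)),
                  ("A08", 4, sorted(lay.core_qsbs)),
                  ("B01", 8, sorted(lay.core_qsbs)),
                  ("N05", 6, [])]
    drugs = []
    did = 0
    for prefix, n_drugs, pool in drug_specs:
        for _ in range(n_drugs):
            did += 1
            code = f"{prefix}{'X' * max(0, 3 - len(prefix))}{rng.integers(10, 99)}"
            t: set = set()
            if pool:
                t |= set(rng.choice(pool, size=min(len(pool), int(rng.integers(2, 6))),
                                    replace=False))
            t |= set(rng.choice(random_target_pool, size=int(rng.integers(1, 5)),
                                replace=False))
            drugs.append(DrugRecord(f"DRUG{did:02d}", (code,), frozenset(t)))

    # PPI over the gene universe, enriched around each syndrome's DPs
    ppi = nx.barabasi_albert_graph(cfg.kb_n_genes, 3, seed=int(rng.integers(2**31)))
    mapping = dict(enumerate(genes))
    ppi = nx.relabel_nodes(ppi, mapping)
    for _, _, d in ppi.edges(data=True):
        d["weight"] = float(np.round(rng.uniform(0.2, 1.0), 3))
    nx.set_node_attributes(ppi, "gene", "kind")
    neighbor_pool = sorted(set(genes) - set(lay.genes_identified) - all_cores)
    for syn in ("CCQS", "QSBS"):
        dps = sorted(lay.dp[syn])
        picks = rng.choice(neighbor_pool, size=12, replace=False)
        for nb in picks:
            for dp_gene in rng.choice(dps, size=min(4, len(dps)), replace=False):
                ppi.add_edge(nb, dp_gene, weight=1.0)

    # metabolite-gene association network from pathway co-membership
    metgene = nx.Graph()
    for term in pathways_genes:
        g_sorted = sorted(pathways_genes[term])
        for m in sorted(pathways_mets.get(term, ())):
            k = min(len(g_sorted), int(rng.integers(2, 5)))
            for gid in rng.choice(g_sorted, size=k, replace=False):
                metgene.add_node(m, kind="metabolite")
                metgene.add_node(gid, kind="gene")
                metgene.add_edge(m, gid, weight=1.0)

    kb = KnowledgeBase(formulae, compounds, set(genes),
                       set(lay.met_ids_unt) | set(lay.met_ids_tgt),
                       pathways_genes, pathways_mets, pathways_joint,
                       chd, diseases, drugs, ppi, metgene)
    gt = GroundTruth(
        formula_targets=gt_formula_targets,
        signature_core={"common": lay.core_common, "CCQS": lay.core_ccqs,
                        "QSBS": lay.core_qsbs},
        related_diseases=related,
        panel_markers=lay.panel_markers,
        planted_pathways=planted_pw,
    )
    return kb, gt


# ---------------------------------------------------------------------------
# serialization of a full run
# ---------------------------------------------------------------------------

def write_run(cfg: SynConfig, outdir: str | Path) -> None:
    """Generate everything and write the plain-text bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    prot, gt = gen_proteomics(cfg)
    prot.to_tsv(outdir / "proteomics.tsv", outdir / "proteomics_meta.tsv")
    unt, tgt, gt_m = gen_metabolomics(cfg)
    unt.to_tsv(outdir / "met_untargeted.tsv", outdir / "met_meta.tsv")
    tgt.to_tsv(outdir / "met_targeted.tsv", outdir / "met_targeted_meta.tsv")
    unt.feature_meta.to_csv(outdir / "met_untargeted_categories.tsv", sep="\t")
    tgt.feature_meta.to_csv(outdir / "met_targeted_categories.tsv", sep="\t")
    kb, gt_k = gen_knowledgebase(cfg)
    gt.merge(gt_m).merge(gt_k)
    gt.to_tsv(outdir / "ground_truth.tsv")

    rows = [(c.compound_id, c.herb_id, c.source,
             "" if c.ob is None else c.ob, "" if c.dl is None else c.dl,
             c.grading or "") for c in kb.compounds]
    pd.DataFrame(rows, columns=["compound", "herb", "source", "ob", "dl", "grading"]).to_csv(
        outdir / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.compound_id, t) for c in kb.compounds for t in sorted(c.targets)],
        columns=["compound", "target"],
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(f.code, h, f.syndrome) for f in kb.formulae for h in f.herbs],
        columns=["code", "herb", "syndrome"],
    ).to_csv(outdir / "formulae.tsv", sep="\t", index=False)
    zio.write_gmt({t: set(s) for t, s in kb.pathways_genes.items()},
                  outdir / "pathways_genes.gmt")
    zio.write_gmt({t: set(s) for t, s in kb.pathways_mets.items()},
                  outdir / "pathways_mets.gmt")
    zio.write_gmt({d.disease_id: set(d.genes) for d in [kb.chd] + kb.diseases},
                  outdir / "disease_genes.gmt")
    zio.write_gmt({d.disease_id: set(d.variants) for d in [kb.chd] + kb.diseases},
                  outdir / "disease_variants.gmt")
    pd.DataFrame(
        [(d.drug_id, ";".join(d.atc_codes), t) for d in kb.drugs for t in sorted(d.targets)],
        columns=["drug", "atc", "target"],
    ).to_csv(outdir / "drugs.tsv", sep="\t", index=False)
    zio.write_sif(kb.ppi, outdir / "ppi.sif", outdir / "ppi_weights.tsv")
    zio.write_sif(kb.metgene, outdir / "metgene.sif", outdir / "metgene_weights.tsv")
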