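"""TCM network pharmacology: active compounds, formula targets, signatures.

Herb ingredients come from three kinds of sources with different activity
rules: TCMSP-style records carry oral bioavailability (OB, %) and
drug-likeness (DL) and are active iff OB >= 30 and DL >= 0.18 (inclusive);
ETCM-style records carry a drug-likeness grading and are active iff it is
good or moderate; pharmacopeia quality markers (Q-markers) are active by
definition.  Per-formula putative target sets are unions over active
compounds; the intersection of the three formulae prescribed for one
syndrome defines that syndrome's signature targets.  Disease relatedness
uses Jaccard indices on shared genes (JIg) and shared variants (JIv) with
strict thresholds, and signature partitions are mapped onto the
pharmacological targets of drugs grouped by ATC-code prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from zhengomics.diffprot import venn_sets

logger = logging.getLogger(__name__)

SOURCES = {"tcmsp", "etcm", "qmarker"}
ACTIVE_GRADINGS = {"good", "moderate"}


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    herb_id: str
    source: str                      # tcmsp | etcm | qmarker
    ob: float | None = None          # oral bioavailability, % (tcmsp)
    dl: float | None = None          # drug-likeness (tcmsp)
    grading: str | None = None       # good | moderate | weak | none (etcm)
    targets: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class FormulaDef:
    code: str                        # F1-1..F2-3
    herbs: tuple
    syndrome: str                    # CCQS | QSBS


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    genes: frozenset
    variants: frozenset


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    atc_codes: tuple
    targets: frozenset


# ---------------------------------------------------------------------------
# activity filtering and target aggregation
# ---------------------------------------------------------------------------

def is_active(rec: CompoundRecord, ob_thresh: float = 30.0, dl_thresh: float = 0.18) -> bool:
    if rec.source == "tcmsp":
        if rec.ob is None or rec.dl is None:
            logger.warning("tcmsp record %s missing OB/DL; rejected", rec.compound_id)
            return False
        return rec.ob >= ob_thresh and rec.dl >= dl_thresh
    if rec.source == "etcm":
        return rec.grading in ACTIVE_GRADINGS
    return True  # qmarker


def filter_active(
    compounds: list[CompoundRecord], ob_thresh: float = 30.0, dl_thresh: float = 0.18
) -> list[CompoundRecord]:
    """Active subset under the per-source rules (idempotent)."""
    return [c for c in compounds if is_active(c, ob_thresh, dl_thresh)]


@dataclass
class FormulaTargets:
    code: str
    targets: set
    n_active: int
    n_active_with_targets: int

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def formula_targets(formula: FormulaDef, active: list[CompoundRecord]) -> FormulaTargets:
    """Union of target sets over a formula's active compounds.

    A compound recorded under several sources counts once; its target sets
    are unioned.  Compounds with an empty target set count toward
    ``n_active`` but not ``n_active_with_targets``.
    """
    herb_set = set(formula.herbs)
    by_compound: dict[str, set] = {}
    for rec in active:
        if rec.herb_id in herb_set:
            by_compound.setdefault(rec.compound_id, set()).update(rec.targets)
    if not by_compound:
        logger.warning("formula %s has no active compounds", formula.code)
    targets: set = set()
    with_targets = 0
    for tset in by_compound.values():
        if tset:
            with_targets += 1
            targets |= tset
    return FormulaTargets(formula.code, targets, len(by_compound), with_targets)


def signature_targets(t1: set, t2: set, t3: set) -> set:
    """Common targets of the three formulae of one syndrome."""
    return set(t1) & set(t2) & set(t3)


def specific_signatures(sig_f1: set, sig_f2: set) -> tuple[set, set, set]:
    """(common, F1-only, F2-only) partition of the two signature sets."""
    return venn_sets(sig_f1, sig_f2)


# ---------------------------------------------------------------------------
# disease similarity
# ---------------------------------------------------------------------------

def jaccard(a: set, b: set) -> float:
    union = set(a) | set(b)
    if not union:
        return 0.0
    return len(set(a) & set(b)) / len(union)


def disease_similarity(
    query: DiseaseRecord,
    candidates: list[DiseaseRecord],
    jig_thresh: float = 0.2,
    jiv_thresh: float = 0.05,
    combine: str = "and",
) -> pd.DataFrame:
    """Diseases related to ``query`` by gene- and variant-sharing.

    JIg and JIv are Jaccard indices on gene and variant sets; a candidate
    is retained iff JIg > jig_thresh AND JIv > jiv_thresh (strict; ``combine
    ='or'`` relaxes to either threshold).
    """
    if combine not in {"and", "or"}:
        raise ValueError("combine must be 'and' or 'or'")
    rows = []
    for cand in candidates:
        jig = jaccard(query.genes, cand.genes)
        jiv = jaccard(query.variants, cand.variants)
        keep = (jig > jig_thresh and jiv > jiv_thresh) if combine == "and" else (
            jig > jig_thresh or jiv > jiv_thresh
        )
        rows.append((cand.disease_id, jig, jiv, keep))
    out = pd.DataFrame(rows, columns=["disease", "jig", "jiv", "related"])
    return out.sort_values(["related", "jig", "disease"], ascending=[False, False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# drug-target overlap by ATC category
# ---------------------------------------------------------------------------

def assign_atc_categories(drug: DrugRecord, prefixes) -> set:
    """ATC categories of a drug: for each code, the longest matching
    configured prefix (case-insensitive); codes with no match contribute
    nothing.  A drug with several codes may land in several categories."""
    cats = set()
    for code in drug.atc_codes:
        best = ""
        for pref in prefixes:
            if code.upper().startswith(pref.upper()) and len(pref) > len(best):
                best = pref
        if best:
            cats.add(best)
    return cats


def map_drug_overlap(
    partitions: dict[str, set],
    drugs: list[DrugRecord],
    atc_prefixes=("C", "A10", "A08", "B01"),
) -> tuple[pd.DataFrame, nx.Graph]:
    """Overlap of signature partitions with ATC-categorised drug targets.

    Returns a (partition x category) table of shared-target counts and a
    bipartite target-drug graph whose edges record (target, drug) pairs
    with the drug's categories as an edge attribute.
    """
    counts = {part: {pref: 0 for pref in atc_prefixes} for part in partitions}
    net = nx.Graph()
    for drug in drugs:
        cats = assign_atc_categories(drug, atc_prefixes)
        if not cats:
            logger.info("drug %s matches no configured ATC prefix; excluded", drug.drug_id)
            continue
        for part, targets in partitions.items():
            shared = set(targets) & set(drug.targets)
            for cat in cats:
                counts[part][cat] += len(shared)
            for t in shared:
                net.add_node(t, kind="target", partition=part)
                net.add_node(drug.drug_id, kind="drug", categories=",".join(sorted(cats)))
                net.add_edge(t, drug.drug_id)
    table = pd.DataFrame(counts).T
    table.index.name = "partition"
    return table, net
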