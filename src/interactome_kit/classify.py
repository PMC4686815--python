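"""RBP functional classification: RNA-linked, RBD-recognised, enigmRBP, enzymes.

An identified RBP is "linked to mRNA biology" when any of its GO term
names contains one of a fixed list of (deliberately truncated)
substrings; it carries a "recognised" RNA-binding domain when any of
its domains is on the classical or non-classical RBD lists supplied as
configuration.  RBPs with neither property are enigmRBPs.  Separately,
genes with EC numbers are flagged as classic metabolic enzymes unless
their descriptors match an exclusion list of RNA/DNA-related enzyme
classes, and tallied by top-level EC class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "AnnotationBundle",
    "RbpClassification",
    "RNA_LINKED_TERMS",
    "DEFAULT_CLASSICAL_RBDS",
    "DEFAULT_NONCLASSICAL_RBDS",
    "DEFAULT_ENZYME_EXCLUSIONS",
    "EC_CLASS_NAMES",
    "classify_rna_linked",
    "classify_rbd",
    "is_enigm_rbp",
    "is_classic_metabolic_enzyme",
    "enzyme_class_breakdown",
    "classify_rbps",
]

logger = logging.getLogger(__name__)

#: GO-name substrings marking a link to mRNA biology.  Several are
#: truncated on purpose to capture multiple word variations
#: ('splic' -> splicing/spliceosome; 'ribosom' -> ribosome/ribosomal).
#: Matching is case-sensitive: 'RNA' must not match inside lowercase words.
RNA_LINKED_TERMS = (
    "mRNA",
    "splic",
    "RNA binding",
    "RNA",
    "RNP",
    "translation",
    "ribosom",
    "nuclease",
    "exosome",
)

#: Default classical / non-classical RNA-binding domain identifiers
#: (Pfam accessions).  These ship only as a convenience starting point;
#: analyses should supply the curated lists used by their domain
#: annotation source.
DEFAULT_CLASSICAL_RBDS = (
    "PF00076",  # RRM
    "PF00013",  # KH
    "PF00270",  # DEAD-box helicase
    "PF00098",  # CCHC zinc knuckle
    "PF00642",  # CCCH zinc finger
    "PF01479",  # S4 domain
    "PF00575",  # S1 domain
)
DEFAULT_NONCLASSICAL_RBDS = (
    "PF00097",  # RING-type zinc finger
    "PF00271",  # helicase C-terminal
    "PF01423",  # LSM
    "PF03880",  # DbpA RNA-binding
    "PF00806",  # Pumilio repeat
    "PF05670",  # NYN/PIN-related
)

#: Case-insensitive descriptor patterns excluding obvious RNA/DNA-related
#: enzymes from the "classic metabolic enzyme" category.
DEFAULT_ENZYME_EXCLUSIONS = (
    "RNA helicase",
    "DNA helicase",
    "tRNA",
    "rRNA",
    "pseudourid",
    "nuclease",
    "aminoacyl",
    "polymerase",
    "topoisomerase",
    "proteasome",
    "regulatory subunit",
)

EC_CLASS_NAMES = {
    1: "oxidoreductases",
    2: "transferases",
    3: "hydrolases",
    4: "lyases",
    5: "isomerases",
    6: "ligases",
}

_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


@dataclass
class AnnotationBundle:
    """Gene-level GO names, domain classes and EC records.

    Genes may be absent from any map and are then treated as
    unannotated.  ``domain_class`` maps gene -> list of
    (domain_id, class_label); ``ec_records`` maps gene -> list of
    (ec_number, descriptor).
    """

    go_names: dict[str, set] = field(default_factory=dict)
    domain_class: dict[str, list] = field(default_factory=dict)
    ec_records: dict[str, list] = field(default_factory=dict)


@dataclass
class RbpClassification:
    gene: str
    rna_linked: bool
    rbd_recognized: bool
    enigm: bool
    classic_enzyme: bool
    ec_top_class: Optional[int] = None

    def __post_init__(self) -> None:
        if self.enigm and (self.rna_linked or self.rbd_recognized):
            raise ValueError("enigmRBP must lack both RNA link and recognised RBD")


def classify_rna_linked(gene: str, bundle: AnnotationBundle) -> bool:
    """True iff any GO term name contains one of the RNA-biology substrings.

    Substring matching is case-sensitive exactly as listed; an
    unannotated gene is 'unknown' in RNA biology (False).
    """
    terms = bundle.go_names.get(gene, set())
    return any(frag in name for name in terms for frag in RNA_LINKED_TERMS)


def classify_rbd(
    gene: str,
    bundle: AnnotationBundle,
    classical_ids: Iterable[str] = DEFAULT_CLASSICAL_RBDS,
    nonclassical_ids: Iterable[str] = DEFAULT_NONCLASSICAL_RBDS,
) -> bool:
    """True iff the gene carries a domain on either RBD list ("recognised")."""
    recognized = set(classical_ids) | set(nonclassical_ids)
    if not recognized:
        logger.warning("empty RBD configuration lists; no domain is recognised")
        return False
    domains = bundle.domain_class.get(gene, [])
    return any(dom_id in recognized for dom_id, _cls in domains)


def is_enigm_rbp(
    gene: str,
    rbp_set: set,
    bundle: AnnotationBundle,
    classical_ids: Iterable[str] = DEFAULT_CLASSICAL_RBDS,
    nonclassical_ids: Iterable[str] = DEFAULT_NONCLASSICAL_RBDS,
) -> bool:
    """An RBP lacking both an RNA-biology GO link and a recognised RBD."""
    if gene not in rbp_set:
        return False
    return not classify_rna_linked(gene, bundle) and not classify_rbd(
        gene, bundle, classical_ids, nonclassical_ids
    )


def is_classic_metabolic_enzyme(
    gene: str,
    bundle: AnnotationBundle,
    exclusion_rules: Iterable[str] = DEFAULT_ENZYME_EXCLUSIONS,
) -> bool:
    """True iff the gene is an enzyme and no record matches an exclusion.

    A gene qualifies when it has at least one well-formed EC record and
    none of its descriptors contains an exclusion pattern
    (case-insensitive).  Malformed EC numbers are skipped with a
    warning.
    """
    records = _valid_ec_records(gene, bundle)
    if not records:
        return False
    patterns = [p.lower() for p in exclusion_rules]
    for _ec, descriptor in records:
        desc = (descriptor or "").lower()
        if any(p in desc for p in patterns):
            return False
    return True


def _valid_ec_records(gene: str, bundle: AnnotationBundle) -> list:
    out = []
    for ec, descriptor in bundle.ec_records.get(gene, []):
        if _EC_RE.match(str(ec).strip()):
            out.append((str(ec).strip(), descriptor))
        else:
            logger.warning("gene %s: malformed EC number %r skipped", gene, ec)
    return out


def enzyme_class_breakdown(genes: Iterable[str], bundle: AnnotationBundle) -> dict[str, int]:
    """Tally genes by top-level EC class (first EC digit).

    A gene with EC numbers in several top classes is counted once per
    distinct class (logged).
    """
    tally = {name: 0 for name in EC_CLASS_NAMES.values()}
    n_multi = 0
    for gene in genes:
        tops = set()
        for ec, _descriptor in _valid_ec_records(gene, bundle):
            top = int(ec.split(".")[0])
            if top in EC_CLASS_NAMES:
                tops.add(top)
        if len(tops) > 1:
            n_multi += 1
        for top in tops:
            tally[EC_CLASS_NAMES[top]] += 1
    if n_multi:
        logger.info("%d genes counted in more than one EC top class", n_multi)
    return tally


def classify_rbps(
    rbp_set: set,
    bundle: AnnotationBundle,
    classical_ids: Iterable[str] = DEFAULT_CLASSICAL_RBDS,
    nonclassical_ids: Iterable[str] = DEFAULT_NONCLASSICAL_RBDS,
    exclusion_rules: Iterable[str] = DEFAULT_ENZYME_EXCLUSIONS,
) -> list[RbpClassification]:
    """Full per-gene classification for every RBP in ``rbp_set``."""
    out = []
    for gene in sorted(rbp_set):
        rna = classify_rna_linked(gene, bundle)
        rbd = classify_rbd(gene, bundle, classical_ids, nonclassical_ids)
        enzyme = is_classic_metabolic_enzyme(gene, bundle, exclusion_rules)
        records = _valid_ec_records(gene, bundle)
        top = None
        if records:
            tops = sorted({int(r[0].split(".")[0]) for r in records})
            top = tops[0] if tops and tops[0] in EC_CLASS_NAMES else None
        out.append(
            RbpClassification(
                gene=gene,
                rna_linked=rna,
                rbd_recognized=rbd,
                enigm=not rna and not rbd,
                classic_enzyme=enzyme,
                ec_top_class=top,
            )
        )
    return out
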