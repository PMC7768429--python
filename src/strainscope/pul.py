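"""Rule-based detection of Polysaccharide Utilization Loci (PUL).

A PUL is anchored by a tandem susC/susD gene pair: a TonB-dependent
outer-membrane transporter gene immediately followed (same strand, in
transcription order) by a surface glycan-binding protein gene.  From each
anchor the locus is extended outwards over nearby genes carrying
"extendable" labels (CAZy families, regulators, peptidases, further
susC/susD copies) subject to gap limits in both base pairs and intervening
gene count.  Loci whose extensions touch are merged, keeping all anchor
pairs — this is how multi-susCD loci arise.

Substrate classification is a majority vote of the member CAZy families'
substrate classes; susC/susD identification and CAZy family labels are
consumed as input annotation, not predicted from sequence.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import FeatureRecord

CAZY_LABEL = re.compile(r"^(GH|PL|CE|GT|AA|CBM)\d+$")

#: Default family -> substrate class map.  GH28 sits at the intersection of
#: pectin and hemicellulose chemistry; it is classed as pectin here because
#: polygalacturonases are the canonical pectin backbone hydrolases.
DEFAULT_SUBSTRATE_MAP: dict[str, str] = {
    **{f: "pectin" for f in ("GH28", "GH2", "GH43", "GH78", "GH105", "GH106", "CE8", "CE12", "PL1")},
    **{f: "hemicellulose/cellulose" for f in ("GH5", "GH16", "GH53", "GH141")},
}


def is_cazy_label(label: str) -> bool:
    return bool(CAZY_LABEL.match(label))


def validate_substrate_map(substrate_map: Mapping[str, str]) -> None:
    for family in substrate_map:
        if not is_cazy_label(family):
            raise ValueError(f"malformed CAZy family label: {family!r}")


@dataclass
class PULParams:
    """Gap rules for anchoring and extension.

    ``max_anchor_gap_genes`` intervening genes are allowed between susC and
    susD (default 1, i.e. susD immediately follows or is one gene away).
    Extension stops once the gap since the last included gene exceeds
    ``max_extension_gap_bp`` or ``max_extension_gap_genes``.
    """

    max_anchor_gap_genes: int = 1
    max_extension_gap_bp: int = 2_000
    max_extension_gap_genes: int = 2
    extendable_labels: frozenset[str] = frozenset({"regulator", "peptidase", "susC", "susD"})

    def __post_init__(self) -> None:
        if min(self.max_anchor_gap_genes, self.max_extension_gap_bp, self.max_extension_gap_genes) < 0:
            raise ValueError("gap limits must be nonnegative")


@dataclass
class PULModel:
    pul_id: str
    anchor_pairs: list[tuple[str, str]]
    member_genes: list[str]
    cazy_families: list[str]
    substrate_class: str = "unassigned"
    substrate_tie: bool = False


@dataclass
class PULSummary:
    n_puls: int
    n_puls_with_ghs: int
    n_gh_in_puls: int
    n_families_in_puls: int
    fraction_families_in_puls: float
    fraction_pul_cazymes_pectin: float


def _is_extendable(feature: FeatureRecord, params: PULParams) -> bool:
    for label in feature.function_labels:
        if label in params.extendable_labels or is_cazy_label(label):
            return True
    return False


def _sorted_genes(features: Iterable[FeatureRecord]) -> list[FeatureRecord]:
    genes = [f for f in features if f.feature_type == "CDS"]
    genes.sort(key=lambda f: (f.start, f.end))
    return genes


def find_suscd_anchors(
    features: Sequence[FeatureRecord], params: PULParams | None = None
) -> list[tuple[str, str]]:
    """Greedy left-to-right pairing of tandem susC/susD genes.

    On the + strand susC must precede susD in genome order; on the - strand
    the transcription order is reversed, so the genome-order pattern is
    susD then susC.  Each gene joins at most one pair.
    """
    params = params or PULParams()
    genes = _sorted_genes(features)
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for i, g in enumerate(genes):
        if g.locus_tag in used:
            continue
        lead_label = "susC" if g.strand == "+" else "susD"
        mate_label = "susD" if g.strand == "+" else "susC"
        if lead_label not in g.function_labels:
            continue
        for j in range(i + 1, min(i + 2 + params.max_anchor_gap_genes, len(genes))):
            mate = genes[j]
            if mate.locus_tag in used or mate.strand != g.strand:
                continue
            if mate_label in mate.function_labels:
                pair = (g.locus_tag, mate.locus_tag) if g.strand == "+" else (mate.locus_tag, g.locus_tag)
                pairs.append(pair)
                used.add(g.locus_tag)
                used.add(mate.locus_tag)
                break
    return pairs


def extend_pul(
    anchor: tuple[str, str],
    features: Sequence[FeatureRecord],
    params: PULParams | None = None,
) -> list[str]:
    """Member locus tags of the locus grown outward from one anchor pair."""
    params = params or PULParams()
    genes = _sorted_genes(features)
    by_tag = {g.locus_tag: k for k, g in enumerate(genes)}
    lo = min(by_tag[anchor[0]], by_tag[anchor[1]])
    hi = max(by_tag[anchor[0]], by_tag[anchor[1]])
    members = set(range(lo, hi + 1))
    for direction in (-1, 1):
        last = lo if direction == -1 else hi
        k = last + direction
        skipped = 0
        while 0 <= k < len(genes) and skipped <= params.max_extension_gap_genes:
            gap_bp = (
                genes[max(k, last)].start - genes[min(k, last)].end - 1
            )
            if gap_bp > params.max_extension_gap_bp:
                break
            if _is_extendable(genes[k], params):
                # skipped interior genes are inside the locus span: keep the
                # membership contiguous
                members.update(range(min(last, k), max(last, k) + 1))
                last = k
                skipped = 0
            else:
                skipped += 1
            k += direction
    return [genes[k].locus_tag for k in sorted(members)]


def classify_substrate(
    cazy_families: Iterable[str],
    substrate_map: Mapping[str, str] | None = None,
) -> tuple[str, bool]:
    """Majority vote over member families' substrate classes.

    Returns (class, tie_flag); ties resolve to the lexicographically first
    class, and loci with no classifiable family are "unassigned".
    """
    substrate_map = DEFAULT_SUBSTRATE_MAP if substrate_map is None else substrate_map
    validate_substrate_map(substrate_map)
    votes = Counter(
        substrate_map[f] for f in cazy_families if f in substrate_map
    )
    if not votes:
        return "unassigned", False
    top = max(votes.values())
    winners = sorted(c for c, v in votes.items() if v == top)
    return winners[0], len(winners) > 1


def call_puls(
    features: Sequence[FeatureRecord],
    params: PULParams | None = None,
    substrate_map: Mapping[str, str] | None = None,
) -> list[PULModel]:
    """Anchor, extend, merge, and classify PULs over one annotation set."""
    params = params or PULParams()
    genes = _sorted_genes(features)
    by_tag = {g.locus_tag: g for g in genes}
    order = {g.locus_tag: k for k, g in enumerate(genes)}
    anchors = find_suscd_anchors(features, params)
    extended = [(a, extend_pul(a, features, params)) for a in anchors]
    # merge loci whose member index ranges share or neighbour each other
    merged: list[tuple[list[tuple[str, str]], set[int]]] = []
    for anchor, members in extended:
        idx = {order[t] for t in members}
        attached = False
        for entry in merged:
            if entry[1] & idx or _adjacent(entry[1], idx):
                entry[0].append(anchor)
                entry[1].update(idx)
                attached = True
                break
        if attached:
            # cascading merges when a locus bridges two earlier ones
            merged = _remerge(merged)
            continue
        merged.append(([anchor], idx))
    puls: list[PULModel] = []
    for n, (anchor_pairs, idx) in enumerate(
        sorted(merged, key=lambda e: min(e[1])), start=1
    ):
        member_tags = [genes[k].locus_tag for k in sorted(idx)]
        families = sorted(
            label
            for tag in member_tags
            for label in by_tag[tag].function_labels
            if is_cazy_label(label)
        )
        substrate, tie = classify_substrate(families, substrate_map)
        puls.append(
            PULModel(
                pul_id=f"PUL_{n:02d}",
                anchor_pairs=sorted(anchor_pairs, key=lambda p: order[p[0]]),
                member_genes=member_tags,
                cazy_families=families,
                substrate_class=substrate,
                substrate_tie=tie,
            )
        )
    return puls


def _adjacent(a: set[int], b: set[int]) -> bool:
    return any(k + 1 in b or k - 1 in b for k in a)


def _remerge(
    entries: list[tuple[list[tuple[str, str]], set[int]]]
) -> list[tuple[list[tuple[str, str]], set[int]]]:
    out: list[tuple[list[tuple[str, str]], set[int]]] = []
    for anchors, idx in entries:
        for entry in out:
            if entry[1] & idx or _adjacent(entry[1], idx):
                entry[0].extend(anchors)
                entry[1].update(idx)
                break
        else:
            out.append((list(anchors), set(idx)))
    return out


def pul_summary(
    puls: Sequence[PULModel],
    genome_family_census: Mapping[str, int],
    substrate_map: Mapping[str, str] | None = None,
) -> PULSummary:
    """Genome-level PUL fractions.

    *genome_family_census* maps every CAZy family in the genome to its gene
    count.  ``fraction_families_in_puls`` is distinct-families-in-PULs over
    distinct-families-in-genome; ``fraction_pul_cazymes_pectin`` is
    pectin-class CAZyme genes inside PULs over all CAZyme genes inside
    PULs.
    """
    if not genome_family_census:
        raise ValueError("empty genome CAZy family census")
    substrate_map = DEFAULT_SUBSTRATE_MAP if substrate_map is None else substrate_map
    fams_in_puls: set[str] = set()
    n_gh = 0
    n_puls_with_ghs = 0
    n_cazy_genes = 0
    n_pectin_genes = 0
    for pul in puls:
        fams_in_puls.update(pul.cazy_families)
        ghs = [f for f in pul.cazy_families if f.startswith("GH")]
        n_gh += len(ghs)
        if ghs:
            n_puls_with_ghs += 1
        for fam in pul.cazy_families:
            n_cazy_genes += 1
            if substrate_map.get(fam) == "pectin":
                n_pectin_genes += 1
    return PULSummary(
        n_puls=len(puls),
        n_puls_with_ghs=n_puls_with_ghs,
        n_gh_in_puls=n_gh,
        n_families_in_puls=len(fams_in_puls),
        fraction_families_in_puls=len(fams_in_puls) / len(genome_family_census),
        fraction_pul_cazymes_pectin=(n_pectin_genes / n_cazy_genes) if n_cazy_genes else 0.0,
    )


def family_census(features: Iterable[FeatureRecord]) -> dict[str, int]:
    """Genome-wide CAZy family -> gene count from annotation labels."""
    census: Counter[str] = Counter()
    for f in features:
        for label in f.function_labels:
            if is_cazy_label(label):
                census[label] += 1
    return dict(census)
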