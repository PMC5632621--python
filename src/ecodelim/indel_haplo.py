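"""Simple indel coding and statistical-parsimony haplotype networks.

Simple indel coding (SIC) turns each distinct internal gap span of an
alignment into one binary presence/absence character: a sequence scores
*present* when it has exactly that gap, *absent* when it has residues
across the span, and *missing* when a longer gap strictly contains the
span (the longer deletion makes the shorter event unobservable).
Terminal gaps are treated as missing data for every character they span.

Haplotype collapsing treats gaps (and N) as missing: two sequences merge
when they agree at every position where both carry a base.  The network
connects haplotypes differing by single mutational steps, inserting
hypothetical intermediate nodes for pairs two or more steps apart, up to
a connection limit beyond which haplotypes stay in separate components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"
MISSING_BASES = {GAP, "N", "?"}


@dataclass
class IndelCharacter:
    """One SIC binary character: the gap spanning [start, end] (1-based)."""

    start: int
    end: int
    scores: dict[str, str]  # seq id -> "1" (present) | "0" (absent) | "?" (missing)


@dataclass
class Haplotype:
    """A distinct sequence variant with its carriers."""

    hap_id: str
    sequence: str  # consensus; missing positions that no member resolves stay as '-'/'N'
    members: list[str]

    @property
    def multiplicity(self) -> int:
        return len(self.members)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA; returns [(id, sequence)], validated."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    validate_alignment(records)
    return records


def validate_alignment(records: list[tuple[str, str]]) -> None:
    if not records:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(f"rows differ in length: {sorted(lengths)}")
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")


def _gap_runs(seq: str) -> list[tuple[int, int, bool]]:
    """Maximal gap runs as (start, end, is_terminal), 1-based inclusive."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == GAP:
            j = i
            while j + 1 < n and seq[j + 1] == GAP:
                j += 1
            runs.append((i + 1, j + 1, i == 0 or j == n - 1))
            i = j + 1
        else:
            i += 1
    return runs


def simple_indel_coding(records: list[tuple[str, str]]) -> list[IndelCharacter]:
    """SIC binary characters for every distinct internal gap span.

    Characters are ordered by (start, end).  Scoring per sequence:
    '1' if the sequence has exactly the span as a maximal gap run, '?'
    if one of its gap runs (internal or terminal) strictly contains the
    span, '0' otherwise.
    """
    validate_alignment(records)
    if len(records) < 2:
        raise ValueError("SIC needs at least 2 sequences")
    runs_by_seq = {sid: _gap_runs(seq) for sid, seq in records}
    spans = sorted({(s, e) for runs in runs_by_seq.values()
                    for s, e, terminal in runs if not terminal})
    characters = []
    for s, e in spans:
        scores = {}
        for sid, _ in records:
            score = "0"
            for rs, re, terminal in runs_by_seq[sid]:
                if (rs, re) == (s, e) and not terminal:
                    score = "1"
                    break
                if rs <= s and e <= re and (rs, re) != (s, e):
                    score = "?"
                    break
            scores[sid] = score
        characters.append(IndelCharacter(start=s, end=e, scores=scores))
    return characters


def sic_to_nexus(records: list[tuple[str, str]], characters: list[IndelCharacter],
                 path: str | Path) -> None:
    """Alignment plus appended SIC binary characters as a NEXUS file."""
    n_sites = len(records[0][1])
    n_indel = len(characters)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(records)} NCHAR={n_sites + n_indel};\n")
        fh.write('  FORMAT DATATYPE=STANDARD MISSING=? GAP=- '
                 'SYMBOLS="ACGT01" INTERLEAVE=NO;\n')
        fh.write("  MATRIX\n")
        for sid, seq in records:
            indels = "".join(c.scores[sid] for c in characters)
            fh.write(f"    {sid.replace(' ', '_')} {seq}{indels}\n")
        fh.write("  ;\nEND;\n")
        fh.write("[SIC characters (1-based alignment spans): "
                 + ", ".join(f"{n_sites + i + 1}=({c.start},{c.end})"
                             for i, c in enumerate(characters))
                 + "]\n")


def _compatible(a: str, b: str) -> bool:
    """True when the sequences agree wherever both carry a base."""
    return all(x == y or x in MISSING_BASES or y in MISSING_BASES
               for x, y in zip(a, b))


def _merge_consensus(a: str, b: str) -> str:
    return "".join(y if x in MISSING_BASES else x for x, y in zip(a, b))


def collapse_haplotypes(records: list[tuple[str, str]]) -> list[Haplotype]:
    """Collapse aligned sequences into haplotypes, gaps/N as missing.

    Exact duplicates group first; groups are then merged greedily in
    order of decreasing multiplicity (ties by lexicographic first id)
    whenever missing-excluded comparison finds no conflicting base.  A
    group compatible with several mutually distinct haplotypes joins the
    higher-multiplicity one (logged).  Haplotype ids are the
    lexicographically first member id.
    """
    validate_alignment(records)
    groups: dict[str, list[str]] = {}
    for sid, seq in records:
        groups.setdefault(seq, []).append(sid)
    proto = sorted(
        ({"seq": seq, "members": sorted(ids)} for seq, ids in groups.items()),
        key=lambda g: (-len(g["members"]), g["members"][0]),
    )
    accepted: list[dict] = []
    for g in proto:
        hits = [h for h in accepted if _compatible(h["seq"], g["seq"])]
        if not hits:
            accepted.append(g)
            continue
        if len(hits) > 1:
            logger.info(
                "collapse_haplotypes: group %s compatible with %d haplotypes; "
                "merged with the largest", g["members"][0], len(hits),
            )
        target = max(hits, key=lambda h: (len(h["members"]), h["members"][0]))
        target["seq"] = _merge_consensus(target["seq"], g["seq"])
        target["members"] = sorted(target["members"] + g["members"])
    return sorted(
        (Haplotype(hap_id=h["members"][0], sequence=h["seq"], members=h["members"])
         for h in accepted),
        key=lambda h: (-h.multiplicity, h.hap_id),
    )


def hamming(a: str, b: str) -> int:
    """Missing-excluded Hamming distance."""
    return sum(1 for x, y in zip(a, b)
               if x != y and x not in MISSING_BASES and y not in MISSING_BASES)


def _mutation_path(a: str, b: str) -> list[str]:
    """Intermediate sequences from a to b, mutating differing positions
    in left-to-right alignment order (deterministic, no biological claim)."""
    diffs = [i for i, (x, y) in enumerate(zip(a, b))
             if x != y and x not in MISSING_BASES and y not in MISSING_BASES]
    seq = list(a)
    out = []
    for i in diffs[:-1]:
        seq[i] = b[i]
        out.append("".join(seq))
    return out


def parsimony_network(haplotypes: list[Haplotype], connection_limit: int = 10) -> nx.Graph:
    """Statistical-parsimony style haplotype network.

    Distance-1 pairs are joined directly; pairs at distance d with
    2 <= d <= connection_limit are joined through d-1 hypothetical
    intermediate nodes, but only when they are not already connected
    (ascending distance, ties by higher multiplicity then id), so no
    redundant long paths are added.  Pairs beyond the limit stay in
    separate components.  Node attributes: ``multiplicity``, ``members``,
    ``hypothetical``, ``sequence``.
    """
    if connection_limit < 1:
        raise ValueError("connection_limit must be >= 1")
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    G = nx.Graph()
    for h in haplotypes:
        G.add_node(h.hap_id, multiplicity=h.multiplicity, members=list(h.members),
                   hypothetical=False, sequence=h.sequence)
    pairs = []
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1:]:
            d = hamming(a.sequence, b.sequence)
            pairs.append((d, -(a.multiplicity + b.multiplicity),
                          min(a.hap_id, b.hap_id), max(a.hap_id, b.hap_id), a, b))
    pairs.sort(key=lambda t: t[:4])
    by_seq = {h.hap_id: h.sequence for h in haplotypes}
    n_hyp = 0
    for d, _, _, _, a, b in pairs:
        if d == 0 or d > connection_limit:
            continue
        if d == 1:
            G.add_edge(a.hap_id, b.hap_id)
            continue
        if nx.has_path(G, a.hap_id, b.hap_id):
            continue
        prev = a.hap_id
        for inter_seq in _mutation_path(a.sequence, b.sequence):
            # reuse an existing node carrying exactly this sequence
            existing = next((nid for nid, s in by_seq.items() if s == inter_seq), None)
            if existing is None:
                node_id = f"hyp{n_hyp}"
                n_hyp += 1
                G.add_node(node_id, multiplicity=0, members=[], hypothetical=True,
                           sequence=inter_seq)
                by_seq[node_id] = inter_seq
                existing = node_id
            G.add_edge(prev, existing)
            prev = existing
        G.add_edge(prev, b.hap_id)
    return G


def network_summary(G: nx.Graph, group_of: dict[str, str]) -> "pd.DataFrame":
    """Distinct-haplotype counts per group and the sharing table.

    ``group_of`` maps member (sequence) ids to group labels; members
    without a label are flagged.  Returns a DataFrame with one row per
    (group, haplotype) incidence; aggregate with value_counts as needed.
    """
    import pandas as pd

    rows = []
    unlabeled = []
    for nid, data in G.nodes(data=True):
        if data.get("hypothetical"):
            continue
        for member in data["members"]:
            grp = group_of.get(member)
            if grp is None:
                unlabeled.append(member)
                continue
            rows.append({"group": grp, "haplotype": nid, "member": member})
    if unlabeled:
        logger.warning("network_summary: %d unlabeled members: %s",
                       len(unlabeled), sorted(unlabeled)[:10])
    df = pd.DataFrame(rows, columns=["group", "haplotype", "member"])
    return df


def haplotypes_per_group(summary: "pd.DataFrame") -> "pd.Series":
    """Number of distinct haplotypes observed in each group."""
    if summary.empty:
        import pandas as pd
        return pd.Series(dtype=int)
    return summary.groupby("group")["haplotype"].nunique()


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    H = G.copy()
    for _, data in H.nodes(data=True):
        data["members"] = ",".join(data.get("members", []))
    nx.write_graphml(H, str(path))


def write_dot(G: nx.Graph, path: str | Path) -> None:
    """Minimal DOT export: node size from multiplicity, dots for
    hypothetical intermediates."""
    with open(path, "w") as fh:
        fh.write("graph haplotypes {\n")
        for nid, data in G.nodes(data=True):
            if data.get("hypothetical"):
                fh.write(f'  "{nid}" [shape=point];\n')
            else:
                fh.write(
                    f'  "{nid}" [label="{nid} (n={data["multiplicity"]})", '
                    f'width={0.3 + 0.1 * data["multiplicity"]:.2f}];\n'
                )
        for u, v in G.edges():
            fh.write(f'  "{u}" -- "{v}";\n')
        fh.write("}\n")
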