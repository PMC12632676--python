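"""Drug-target overlay and evidence-network assembly.

Classifies each prioritized protein's druggability (direct target,
secondary via a high-confidence first-shell interactor, or none) and
builds a typed graph linking drugs, proteins, the kidney outcome, and
phenome associations. Graphs are networkx objects exported as GraphML
plus flat node/edge tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = ["classify_druggability", "build_network", "network_summary",
           "export_network", "import_network"]


def classify_druggability(
    protein: str,
    drug_targets: pd.DataFrame,
    ppi: pd.DataFrame,
    score_min: float = 0.9,
) -> str:
    """{direct, secondary, none} for one protein.

    direct: some drug targets the protein itself; secondary: a first-shell
    PPI interactor with confidence >= ``score_min`` is a drug target;
    otherwise none. A protein absent from the PPI table simply has no
    interactors.
    """
    targets = set(drug_targets["target"].astype(str))
    if protein in targets:
        return "direct"
    mask_a = ppi["protein_a"].astype(str) == protein
    mask_b = ppi["protein_b"].astype(str) == protein
    strong = ppi["score"].astype(float) >= score_min
    interactors = set(ppi.loc[mask_a & strong, "protein_b"].astype(str)) | set(
        ppi.loc[mask_b & strong, "protein_a"].astype(str)
    )
    if interactors & targets:
        return "secondary"
    return "none"


def build_network(
    verdicts: Iterable,
    profiles: Dict[str, "object"],
    drug_targets: pd.DataFrame,
    ppi: pd.DataFrame,
    score_min: float = 0.9,
    outcome_label: str = "kidney_outcome",
) -> nx.Graph:
    """Evidence network over the prioritized proteins.

    One connected component per protein: the protein node, its kidney
    outcome edge carrying the signed MR direction, its significant phecode
    nodes, drugs targeting it directly, and drugs reachable through
    high-confidence interactors (with the ``interacts`` edge carrying its
    confidence score). No self-loops; only interacts edges at or above
    ``score_min`` are included.
    """
    G = nx.Graph()
    targets_by_drug = drug_targets.groupby("target")["drug"].apply(list).to_dict()

    for v in verdicts:
        prot = v.protein_id
        G.add_node(prot, node_type="protein",
                   druggability=classify_druggability(prot, drug_targets, ppi, score_min))
        out_node = f"{outcome_label}:{prot}"
        G.add_node(out_node, node_type="kidney_outcome")
        sign = 0.0
        for res in v.endpoint_results.values():
            sign = float(res.beta)
            break
        G.add_edge(prot, out_node, edge_type="mr_association",
                   sign=1.0 if sign >= 0 else -1.0, acat_p=float(v.acat_p))

        for drug in targets_by_drug.get(prot, []):
            G.add_node(drug, node_type="drug")
            G.add_edge(drug, prot, edge_type="targets")

        mask = (ppi["protein_a"].astype(str) == prot) | (ppi["protein_b"].astype(str) == prot)
        for _, row in ppi[mask].iterrows():
            score = float(row["score"])
            if score < score_min:
                continue
            partner = row["protein_b"] if str(row["protein_a"]) == prot else row["protein_a"]
            partner = str(partner)
            if partner == prot:
                continue
            G.add_node(partner, node_type="protein")
            G.add_edge(prot, partner, edge_type="interacts", score=score)
            for drug in targets_by_drug.get(partner, []):
                G.add_node(drug, node_type="drug")
                G.add_edge(drug, partner, edge_type="targets")

        profile = profiles.get(prot)
        if profile is not None:
            for code, dom in zip(profile.hit_phecodes, _domains_for(profile)):
                node = f"phecode:{code}"
                G.add_node(node, node_type="phecode", domain=dom)
                G.add_edge(prot, node, edge_type="phewas_association", sign=1.0)
    return G


def _domains_for(profile) -> list:
    # hit_domains is the unique set; map each phecode to a domain if lengths
    # line up, else repeat the first
    if len(profile.hit_domains) == len(profile.hit_phecodes):
        return profile.hit_domains
    return [profile.hit_domains[0] if profile.hit_domains else "unknown"] * len(profile.hit_phecodes)


def network_summary(G: nx.Graph) -> dict:
    """Unique drug / target / pair counts over the drug→protein edges."""
    pairs = [
        tuple(sorted(e)) for e, d in nx.get_edge_attributes(G, "edge_type").items()
        if d == "targets"
    ]
    drugs = {n for n, d in G.nodes(data=True) if d.get("node_type") == "drug"}
    targeted = set()
    for u, v, d in G.edges(data=True):
        if d.get("edge_type") == "targets":
            targeted.add(v if u in drugs else u)
    return {
        "n_drugs": len(drugs),
        "n_targets": len(targeted),
        "n_pairs": len(set(pairs)),
        "n_proteins": sum(1 for _, d in G.nodes(data=True) if d.get("node_type") == "protein"),
    }


def export_network(G: nx.Graph, out_dir: str | Path, stem: str = "evidence_network") -> None:
    """Write GraphML plus flat node/edge TSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(G, out_dir / f"{stem}.graphml")
    nodes = pd.DataFrame(
        [{"node": n, **d} for n, d in G.nodes(data=True)]
    )
    edges = pd.DataFrame(
        [{"source": u, "target": v, **d} for u, v, d in G.edges(data=True)]
    )
    nodes.to_csv(out_dir / f"{stem}_nodes.tsv", sep="\t", index=False)
    edges.to_csv(out_dir / f"{stem}_edges.tsv", sep="\t", index=False)


def import_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
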