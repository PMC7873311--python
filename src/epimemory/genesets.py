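"""Direction-stratified gene lists and hypergeometric gene-set enrichment.

Stands in for web-service pathway tools with a documented one-sided
hypergeometric test over an array-constrained gene universe.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from epimemory.datamodel import PROMOTER_REGIONS, ValidationError
from epimemory.ewas import ConsensusCpGs, bh_adjust

GENE_LIST_CATEGORIES = ("GA_pos", "GA_neg", "SD_pos", "SD_neg")


def build_gene_lists(
    consensus: ConsensusCpGs,
    manifest: pd.DataFrame,
    min_cpgs_per_gene: int = 2,
) -> dict[str, pd.DataFrame]:
    """Map promoter-region consensus CpGs to genes, per direction category.

    Gene-body, 3'UTR and intergenic probes (and probes without a gene) are
    excluded; a gene qualifies with at least ``min_cpgs_per_gene``
    supporting promoter CpGs in the category.
    """
    ann = manifest.set_index("probe_id")
    missing = [p for frame in (consensus.ga_related, consensus.sd_related)
               for p in frame["probe_id"] if p not in ann.index]
    if missing:
        raise ValidationError(f"manifest lacks consensus probes: {missing[:5]}")

    out: dict[str, pd.DataFrame] = {}
    for prefix, frame in (("GA", consensus.ga_related), ("SD", consensus.sd_related)):
        for sign, suffix in ((1, "pos"), (-1, "neg")):
            probes = frame.loc[frame["sign"] == sign, "probe_id"]
            sub = ann.loc[ann.index.intersection(probes)]
            sub = sub[sub["gene_region"].isin(PROMOTER_REGIONS) & (sub["gene"] != "")]
            counts = sub.groupby("gene").size()
            counts = counts[counts >= min_cpgs_per_gene].sort_index()
            out[f"{prefix}_{suffix}"] = pd.DataFrame(
                {"gene": counts.index, "n_cpgs": counts.to_numpy()})
    return out


def hypergeom_enrich(
    gene_list,
    collection: dict[str, set[str]],
    universe,
    enrichment_fdr: float = 0.1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each collection set.

    Sets are intersected with the universe first; BH q-values flag rows
    significant at the configured enrichment FDR.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    genes = set(gene_list) & universe
    if set(gene_list) - universe:
        raise ValidationError("gene list contains genes outside the universe")
    N, n = len(universe), len(genes)

    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        K = len(members)
        k = len(members & genes)
        # P(overlap >= k) under hypergeometric sampling of the list
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "list_size": n, "universe_size": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] <= enrichment_fdr
    return df
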