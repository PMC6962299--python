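"""Differential co-expression: gene pairs strongly correlated only in the
altered (or only in the non-altered) samples of a PDSG."""

from pdsgscreen import build_network, diff_coex_edges, \
    default_paper_like_config, simulate_cohort

cohort = simulate_cohort(default_paper_like_config(seed=0))
pdsgs = [f"G{i:04d}" for i in range(6)]

edges = diff_coex_edges(cohort, pdsgs, x=0.3, hi=0.5, lo=0.1)
net = build_network(edges)
counts = net.edge_counts_by_class()
print(f"{len(edges)} differentially co-expressed pairs "
      f"({counts['alteration']} active in altered samples, "
      f"{counts['non_alteration']} in non-altered)")
top = sorted(net.degree.items(), key=lambda kv: -kv[1])[:3]
print("highest-degree nodes:",
      ", ".join(f"{g} (degree {d})" for g, d in top))
print(f"connected components: {net.n_components}")
# An edge means |r| > 0.5 in one sample class but < 0.1 in the other:
# a co-regulation that switches on (or off) with the copy-number event.
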