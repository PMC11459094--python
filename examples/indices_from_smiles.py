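"""Compute the nine degree-based topological indices of epinephrine.

Parses the SMILES string into a hydrogen-suppressed graph, reduces it to
its degree-pair edge partition, and evaluates each index as a
count-weighted sum over the partition.
"""

from toporank import compute_all, edge_partition, parse_smiles
from toporank.indices import INDEX_ORDER

graph = parse_smiles("CNCC(O)c1ccc(O)c(O)c1")  # epinephrine, 13 heavy atoms
partition = edge_partition(graph)

print(f"heavy atoms: {graph.n_vertices}, bonds: {graph.n_edges}")
print("edge partition (degree pair -> count):")
for (a, b), count in partition.items():
    print(f"  ({a},{b}): {count}")

values = compute_all(partition)
print("\ntopological indices:")
for name in INDEX_ORDER:
    print(f"  {name.value:>4} = {values[name]:.6f}")

# The partition says e.g. five bonds join a degree-2 atom to a degree-3
# atom; M1 sums degree pairs (60), M2 their products (67), and HM always
# equals F + 2*M2 (286 = 152 + 134).
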