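"""Build spatial adjacency graphs: from polygons, an edge list, or a lattice.

The CAR prior needs a symmetric neighbour graph over the analysis units;
this shows the three ways to construct one and the invariants it satisfies.
"""

from shapely.geometry import box

from smrmap import (
    build_adjacency_from_edgelist,
    build_adjacency_from_polygons,
    generate_lattice_graph,
)

# queen contiguity on a 2x2 block of unit squares: corner touches count,
# so every square neighbours every other
squares = {name: box(x, y, x + 1, y + 1)
           for name, (x, y) in zip("abcd", [(0, 0), (1, 0), (0, 1), (1, 1)])}
g_queen = build_adjacency_from_polygons(squares, rule="queen")
g_rook = build_adjacency_from_polygons(squares, rule="rook")
print("queen degrees:", list(g_queen.degrees), "| rook degrees:", list(g_rook.degrees))

# an explicit edge list; units absent from all edges stay as islands
g_edges = build_adjacency_from_edgelist([("A", "B"), ("B", "C")], ["A", "B", "C", "D"])
print("edge-list graph:", g_edges.n_units, "units,", g_edges.n_edges,
      "edges,", g_edges.n_components, "components (D is an island)")

# a rook lattice standing in for a municipality mosaic
lattice = generate_lattice_graph(20, 20)
print(f"20x20 lattice: {lattice.n_units} units, {lattice.n_edges} edges "
      "(= 20*19 horizontal + 19*20 vertical)")
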