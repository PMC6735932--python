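# Geometric base-pairing criteria.
#
# Each criterion names residue roles (accepted residue names per role) and
# a list of clauses; a candidate base pair (or triplet) satisfies the
# criterion when EVERY clause holds, and a clause holds when ANY of its
# alternative atom-distance conditions is met.  Hydrogen-based conditions
# (H...acceptor <= 2.5 A) apply when the structure carries hydrogens;
# the heavy-atom fallbacks (donor...acceptor <= 3.5 A) cover crystal-derived
# models without hydrogens.
criteria:
  - label: WC_AT
    roles:
      a: [DA, A, ADE]
      b: [DT, T, THY]
    clauses:
      - - {i: a, atom_i: H61, j: b, atom_j: O4, max: 2.5}
        - {i: a, atom_i: N6, j: b, atom_j: O4, max: 3.5}
      - - {i: b, atom_i: H3, j: a, atom_j: N1, max: 2.5}
        - {i: b, atom_i: N3, j: a, atom_j: N1, max: 3.5}
  - label: HG_AT
    # Hoogsteen A:T — adenine N7/N6 face paired with thymine N3(H3)/O2.
    roles:
      a: [DA, A, ADE]
      b: [DT, T, THY]
    clauses:
      - - {i: b, atom_i: H3, j: a, atom_j: N7, max: 2.5}
        - {i: b, atom_i: N3, j: a, atom_j: N7, max: 3.5}
      - - {i: a, atom_i: H61, j: b, atom_j: O2, max: 2.5}
        - {i: a, atom_i: H62, j: b, atom_j: O2, max: 2.5}
        - {i: a, atom_i: N6, j: b, atom_j: O2, max: 3.5}
  - label: R_TRIPLET
    # R-type base triplet: one thymine from each of the incoming (role a)
    # and outgoing (role c) strands around one complementary-strand
    # adenine (role b).
    roles:
      a: [DT, T, THY]
      b: [DA, A, ADE]
      c: [DT, T, THY]
    clauses:
      - - {i: b, atom_i: H61, j: a, atom_j: O4, max: 2.5}
        - {i: a, atom_i: H3, j: b, atom_j: N1, max: 2.5}
        - {i: b, atom_i: N6, j: a, atom_j: O4, max: 3.5}
        - {i: a, atom_i: N3, j: b, atom_j: N1, max: 3.5}
      - - {i: b, atom_i: H62, j: c, atom_j: O4, max: 2.5}
        - {i: b, atom_i: N6, j: c, atom_j: O4, max: 3.5}
      - - {i: c, atom_i: H3, j: a, atom_j: O4, max: 2.5}
        - {i: c, atom_i: N3, j: a, atom_j: O4, max: 3.5}
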