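# utrfold reduced nearest-neighbor free-energy parameters (kcal/mol, 37 C).
#
# This is a deliberately compact parameter set: Watson-Crick + GU wobble
# dinucleotide stacks, loop-length initiation penalties with
# Jacobson-Stockmayer extrapolation beyond the tabulated sizes, and an
# affine multibranch-loop penalty (offset + per-branch + per-unpaired).
# Dangling ends, terminal-pair penalties, special hairpin sequences and
# coaxial stacking are intentionally absent.  Correctness of the folding
# engine is defined against exhaustive enumeration under *these* tables,
# not against any external parameter set.
#
# SHAPE pseudo-free-energy: dG_SHAPE(S) = slope * ln(S + 1) + intercept,
# added once per paired nucleotide per helix stack it participates in
# (helix-internal nucleotides therefore accumulate the term twice, helix
# ends once).  Nucleotides without data contribute 0.

temperature_k: 310.15

# stack[XY][WZ]: pair (i,j) = X:Y closing over pair (i+1,j-1) = W:Z,
# X = seq[i], Y = seq[j], W = seq[i+1], Z = seq[j-1].
stack:
  AU: {AU: -0.9, CG: -2.2, GC: -2.1, GU: -0.6, UA: -1.1, UG: -1.4}
  CG: {AU: -2.1, CG: -3.3, GC: -2.4, GU: -1.4, UA: -2.1, UG: -2.1}
  GC: {AU: -2.4, CG: -3.4, GC: -3.3, GU: -1.5, UA: -2.2, UG: -2.5}
  GU: {AU: -1.3, CG: -2.5, GC: -2.1, GU: -0.5, UA: -1.4, UG: +1.3}
  UA: {AU: -1.3, CG: -2.4, GC: -2.1, GU: -1.0, UA: -0.9, UG: -1.3}
  UG: {AU: -1.0, CG: -1.5, GC: -1.4, GU: +0.3, UA: -0.6, UG: -0.5}

# hairpin initiation by loop size, sizes 3..9; larger sizes extrapolated as
# dG(n) = dG(9) + 1.75 * R * T * ln(n / 9)
hairpin: [5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4]

# bulge initiation by total unpaired, sizes 1..6; JS extrapolation beyond
bulge: [3.8, 2.8, 3.2, 3.6, 4.0, 4.4]

# internal-loop initiation by total unpaired (n1 + n2 >= 2), sizes 2..9;
# JS extrapolation beyond
internal: [1.5, 1.8, 2.0, 2.2, 2.5, 2.7, 2.9, 3.1]

multibranch:
  offset: 3.4        # closing a multibranch loop
  per_branch: 0.4    # each helix entering the loop, including the closing one
  per_unpaired: 0.0  # each unpaired nucleotide inside the loop

min_hairpin: 3          # minimum hairpin loop size (j - i >= 4)
max_internal: 30        # largest total unpaired in a bulge/internal loop the DPs search
max_pairing_dist: 600   # maximum pair span j - i

shape_slope: 1.8        # kcal/mol, m in m*ln(S+1) + b
shape_intercept: -0.6   # kcal/mol
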