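"""Central numeric defaults shared across modules.

All quantities are expressed on the genetic (Morgan) scale of the gamete,
where a bivalent carries on average ``BIVALENT_INTENSITY`` crossovers per
Morgan.
"""

#: Crossovers per Morgan on a bivalent (2 COs per Morgan = 1 per gamete).
#: This is a modelling convention, not a tunable parameter.
BIVALENT_INTENSITY = 2.0

#: Admissible box for the gamma shape (interference strength) during fitting.
NU_MIN = 0.1
NU_MAX = 50.0

#: Number of grid cells used to discretize a map when no explicit
#: ``grid_step`` is requested (grid_step = span / GRID_CELLS).
GRID_CELLS = 2000

#: Coarser resolution used inside iterative fitting, where the statistical
#: error of the data dwarfs the quadrature error.
FIT_GRID_CELLS = 500

#: Tail mass allowed beyond ``kmax`` in the CO-count distribution.
COUNT_TAIL_TOL = 1e-6

#: Number of Gauss-Legendre nodes for the count-distribution integrals.
COUNT_QUAD_NODES = 400

#: Floor for pattern probabilities inside log-likelihoods (guards against
#: quadrature round-off on astronomically unlikely patterns).
PROB_FLOOR = 1e-300

#: Default simulated population size for the projected-likelihood score.
SCORE_N_SIM = 10**6

#: Default histogram binning: CO counts 0..KMAX, positions, inter-CO distances.
HIST_KMAX = 15
HIST_POS_BINS = 10
HIST_DIST_BINS = 20

#: Empirical-CDF bins for physical-to-genetic conversion.
CDF_BINS = 50
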