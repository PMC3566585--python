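"""Single authoritative source for every numerical convention in the package.

All prior means/variances, hemodynamic constants and solver defaults live
here so that a change of convention is a one-line edit.  Units are Hz for
rate constants, seconds for times, and natural log units (nats) for
precisions and evidence.
"""

# --------------------------------------------------------------------------
# Priors on the endogenous coupling matrix A (entries in Hz).
#
# Self-connections shrink towards -1/2 Hz; between-node connections towards a
# small positive value.  Prior precision scales with the number of nodes n so
# that densely connected large models cannot develop runaway excitation:
#   self:     N(-1/2, 1/(8 n))
#   between:  N(1/(64 n), 8/n)
A_SELF_PRIOR_MEAN = -0.5


def a_self_prior_variance(n_nodes: int) -> float:
    return 1.0 / (8.0 * n_nodes)


def a_between_prior_mean(n_nodes: int) -> float:
    return 1.0 / (64.0 * n_nodes)


def a_between_prior_variance(n_nodes: int) -> float:
    return 8.0 / n_nodes


# Driving-input efficacy (C): free only for driven nodes.
C_PRIOR_MEAN = 0.0
C_PRIOR_VARIANCE = 1.0

# Bilinear (B) parameters are carried in the parameter vector for
# completeness but are fixed at zero by default (zero prior variance).
B_PRIOR_MEAN = 0.0
B_PRIOR_VARIANCE = 0.0

# --------------------------------------------------------------------------
# Hemodynamic (balloon-Windkessel) constants.  Fixed physiological values;
# per-node free parameters are log-scaling factors on decay and transit plus
# a global log-scaling on the intra/extravascular ratio epsilon.
HEMO_SIGNAL_DECAY = 0.64      # kappa, 1/s
HEMO_AUTOREGULATION = 0.32    # gamma, 1/s
HEMO_TRANSIT_TIME = 2.0       # tau, s
HEMO_STIFFNESS_ALPHA = 0.32   # Grubb's exponent, dimensionless
HEMO_OXYGEN_EXTRACTION = 0.4  # E0, resting extraction fraction
HEMO_EFFICACY = 1.0           # neurovascular efficacy (fixed)
HEMO_EPSILON = 1.0            # intra/extravascular signal ratio at scale 0

# BOLD observation equation (1.5 T single-compartment convention).
BOLD_V0 = 4.0                 # resting venous volume fraction (percent)
BOLD_THETA0 = 40.3            # frequency offset at the outer surface, 1/s
BOLD_R0 = 25.0                # intravascular relaxation slope, 1/s
DEFAULT_TE = 0.05             # echo time, s

# Prior variance of the per-node log-scaling hemodynamic parameters.
HEMO_SCALE_PRIOR_MEAN = 0.0
HEMO_DECAY_SCALE_PRIOR_VARIANCE = 1.0 / 256.0
HEMO_TRANSIT_SCALE_PRIOR_VARIANCE = 1.0 / 256.0
HEMO_EPSILON_SCALE_PRIOR_VARIANCE = 1.0 / 256.0

# --------------------------------------------------------------------------
# Hyperpriors on the per-node log precision of observation noise.
LOG_PRECISION_PRIOR_MEAN = 4.0
LOG_PRECISION_PRIOR_VARIANCE = 1.0 / 8.0

# --------------------------------------------------------------------------
# Numerics.
MICROTIME_STEPS_PER_TR = 16          # default microtime resolution
PRIOR_RANK_TOL = 1e-8                # relative eigenvalue cut for support
FD_RELATIVE_STEP = 1e-4              # central-difference step (prior-sd units)
CONVERGENCE_DF = 1e-2                # nats; must hold 3 consecutive times
CONVERGENCE_STREAK = 3
MAX_ITERATIONS = 128
PRUNED_EDGE_PRIOR_VARIANCE = 1e-8    # "absent edge" prior variance
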