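# Default two-state model profile (dimensionless model units).
# Calibrated once to reproduce the qualitative switching-frequency regimes:
# push (net x > 0) at low f, pull (net x < 0, larger |x|) at intermediate f,
# minimal |x| at high f, lifetime nondecreasing in f, and push-only under
# the momentum-exchange ablation.  See docs/methods.md for the calibration.
A_max: 0.05        # max UV disassembly ratio (1/time)
lambda_max: 1.0    # UV disengagement saturates at total loss (long intervals)
B: 0.3             # Vis reassociation ratio (1/time), constant
kappa: 0.05        # Vis disengagement ratio, constant
tau_star: 8.0      # characteristic diffusion time t* = 800 * dt
dt: 0.01           # explicit-Euler step
v_eject: 1.0       # UV-discharged flow speed relative to the Liquid domain
v_reverse: 5.0     # Vis reversing-flow speed toward the ROI
gamma: 0.2         # viscous drag rate on the Liquid velocity (1/time)
beta: 0.1          # diffusive momentum-decay rate of the Dissociated pool
exchange_enabled: true
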