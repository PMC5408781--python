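{
 "hybridC": {
  "circuit": {
   "schema_version": 1,
   "topology": {
    "intra": [
     [
      0,
      1
     ],
     [
      0,
      0
     ]
    ],
    "inter": [
     -1,
     1
    ],
    "signaling": 0
   },
   "params": {
    "intra_w": [
     [
      0.0,
      0.41
     ],
     [
      0.0,
      0.0
     ]
    ],
    "inter_w": [
     -0.3,
     5.49
    ],
    "alpha": [
     12.79,
     6.93
    ],
    "beta": 5.0
   }
  },
  "trigger_gene": 1,
  "context_gene": 0,
  "function_map": {
   "0.0": "inhibition",
   "1.0": "induction"
  },
  "dynamics_class": "attractor_switching",
  "neighbor_mode": "mean",
  "notes": "Union of the activate-activator induction core and the mutual-repression inhibition core; assignment resolved by phase-portrait + tissue calibration over all sign-compatible label assignments."
 },
 "AI1": {
  "circuit": {
   "schema_version": 1,
   "topology": {
    "intra": [
     [
      0,
      1
     ],
     [
      -1,
      1
     ]
    ],
    "inter": [
     -1,
     0
    ],
    "signaling": 0
   },
   "params": {
    "intra_w": [
     [
      0.0,
      6.47
     ],
     [
      -7.98,
      9.61
     ]
    ],
    "inter_w": [
     -0.05,
     0.0
    ],
    "alpha": [
     6.81,
     6.4
    ],
    "beta": 10.0
   }
  },
  "trigger_gene": 1,
  "context_gene": 0,
  "function_map": {
   "0.0": "induction",
   "1.0": "inhibition"
  },
  "dynamics_class": "pursuit",
  "neighbor_mode": "mean",
  "notes": "A two-link inhibition core plus auto-activation of the cell-autonomous gene and repression of it by the signaling gene; contains an inhibition module but no induction module (emergent). Induction proceeds by pursuit of a moving attractor. Assignment resolved by behavior calibration."
 },
 "Gprime": {
  "circuit": {
   "schema_version": 1,
   "topology": {
    "intra": [
     [
      1,
      -1
     ],
     [
      0,
      0
     ]
    ],
    "inter": [
     1,
     1
    ],
    "signaling": 0
   },
   "params": {
    "intra_w": [
     [
      3.22,
      -4.93
     ],
     [
      0.0,
      0.0
     ]
    ],
    "inter_w": [
     0.43,
     0.14
    ],
    "alpha": [
     8.62,
     15.86
    ],
    "beta": 5.0
   }
  },
  "trigger_gene": 0,
  "context_gene": 1,
  "function_map": {
   "0.0": "induction"
  },
  "dynamics_class": "ramp",
  "neighbor_mode": "mean",
  "notes": "Union of the intercellular-auto-activation induction core and the activate-inhibitor core, plus auto-regulation of the signaling gene (hybrid). A smooth context ramp 0->1 abruptly converts the induced uniform field into an alternating pattern via a subcritical pitchfork; a static C=1 run from the uniform start stays unpatterned (hysteresis), so only the C=0 verdict is part of the static function map."
 }
}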