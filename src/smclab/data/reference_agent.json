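{
  "w11": 9.089056071292617,
  "w21": -3.2691460037465205,
  "theta1": -4.751513977814714,
  "theta2": 2.6357939110666315,
  "tau1": 0.3738548972541008,
  "tau2": 3.6968813211240867,
  "g_s": 39.743921639079346,
  "v_max": 1.0,
  "provenance": {
    "package_version": "0.1.0",
    "evolution_seed": 47,
    "fitness": 0.9775763740737681,
    "discrimination_success": 1.0,
    "genome": [
      0.7840330022278943,
      0.39783918738292123,
      0.3515151881932902,
      0.5823685597208322,
      0.027662110833747554,
      0.36332134556808954,
      0.8974392163907935
    ],
    "selection": "warm-started GA run; selected among successful evolved agents for the oscillatory-approach / single-reversal-avoidance solution class with a four-region attractor landscape and no slow attractor"
  }
}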