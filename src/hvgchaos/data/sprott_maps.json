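{
  "logistic": {
    "family": "noninvertible",
    "params": {"a": 4.0},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> a x (1 - x); fully developed chaos at a = 4"
  },
  "sine": {
    "family": "noninvertible",
    "params": {"a": 1.0},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> a sin(pi x)"
  },
  "tent": {
    "family": "noninvertible",
    "params": {"a": 1.99999},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> a min(x, 1 - x); a kept just below 2 so the binary-shift orbit does not collapse to 0 in floating point"
  },
  "linear_congruential": {
    "family": "noninvertible",
    "params": {"a": 7141.0, "b": 54773.0, "c": 259200.0},
    "x0": [0.0],
    "coords": ["x"],
    "note": "x -> (a x + b) mod c"
  },
  "cubic": {
    "family": "noninvertible",
    "params": {"a": 3.0},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> a x (1 - x^2)"
  },
  "ricker": {
    "family": "noninvertible",
    "params": {"a": 20.0},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> a x exp(-x); Ricker's population model"
  },
  "gauss": {
    "family": "noninvertible",
    "params": {},
    "x0": [0.23],
    "coords": ["x"],
    "note": "x -> 1/x mod 1 (continued-fraction map); x0 chosen so no iterate rounds onto an integer reciprocal"
  },
  "cusp": {
    "family": "noninvertible",
    "params": {"a": 2.0},
    "x0": [0.5],
    "coords": ["x"],
    "note": "x -> 1 - a sqrt(|x|)"
  },
  "pinchers": {
    "family": "noninvertible",
    "params": {"s": 2.0, "c": 0.5},
    "x0": [0.0],
    "coords": ["x"],
    "note": "x -> |tanh(s (x - c))|"
  },
  "spence": {
    "family": "noninvertible",
    "params": {},
    "x0": [0.5],
    "coords": ["x"],
    "note": "x -> |ln x|"
  },
  "sine_circle": {
    "family": "noninvertible",
    "params": {"omega": 0.5, "k": 2.0},
    "x0": [0.1],
    "coords": ["x"],
    "note": "x -> x + omega - (k/2pi) sin(2 pi x) mod 1"
  },
  "henon": {
    "family": "dissipative",
    "params": {"a": 1.4, "b": 0.3},
    "x0": [0.0, 0.9],
    "coords": ["x", "y"],
    "note": "x -> 1 - a x^2 + b y; y -> x"
  },
  "lozi": {
    "family": "dissipative",
    "params": {"a": 1.7, "b": 0.5},
    "x0": [-0.1, 0.1],
    "coords": ["x", "y"],
    "note": "x -> 1 - a |x| + b y; y -> x"
  },
  "delayed_logistic": {
    "family": "dissipative",
    "params": {"a": 2.27},
    "x0": [0.001, 0.001],
    "coords": ["x", "y"],
    "note": "x -> a x (1 - y); y -> x (one delayed coordinate)"
  },
  "tinkerbell": {
    "family": "dissipative",
    "params": {"a": 0.9, "b": -0.6013, "c": 2.0, "d": 0.5},
    "x0": [0.0, 0.5],
    "coords": ["x", "y"],
    "note": "x -> x^2 - y^2 + a x + b y; y -> 2 x y + c x + d y"
  },
  "burgers": {
    "family": "dissipative",
    "params": {"a": 0.75, "b": 1.75},
    "x0": [-0.1, 0.1],
    "coords": ["x", "y"],
    "note": "x -> a x - y^2; y -> b y + x y"
  },
  "holmes": {
    "family": "dissipative",
    "params": {"b": 0.2, "d": 2.77},
    "x0": [1.6, 0.0],
    "coords": ["x", "y"],
    "note": "Holmes cubic map: x -> y; y -> -b x + d y - y^3"
  },
  "dissipative_standard": {
    "family": "dissipative",
    "params": {"b": 0.1, "k": 8.8},
    "x0": [0.1, 0.1],
    "coords": ["x", "y"],
    "note": "y -> b y + k sin x; x -> x + y' (both mod 2 pi)"
  },
  "ikeda": {
    "family": "dissipative",
    "params": {"alpha": 6.0, "beta": 0.4, "gamma": 1.0, "mu": 0.9},
    "x0": [0.0, 0.0],
    "coords": ["x", "y"],
    "note": "phi = beta - alpha/(1 + x^2 + y^2); rotation by phi, contraction mu, shift gamma"
  },
  "sinai": {
    "family": "dissipative",
    "params": {"delta": 0.1},
    "x0": [0.5, 0.5],
    "coords": ["x", "y"],
    "note": "x -> x + y + delta cos(2 pi y) mod 1; y -> x + 2 y mod 1"
  },
  "predator_prey": {
    "family": "dissipative",
    "params": {"r": 3.0, "alpha": 5.0},
    "x0": [0.5, 0.5],
    "coords": ["x", "y"],
    "note": "discrete predator-prey: x -> x exp(r (1 - x) - alpha y); y -> x (1 - exp(-alpha y))"
  },
  "chirikov": {
    "family": "conservative",
    "params": {"k": 1.0},
    "x0": [0.0, 6.0],
    "coords": ["x", "y"],
    "note": "Chirikov standard map: y -> y + k sin x; x -> x + y' (both mod 2 pi)"
  },
  "henon_area": {
    "family": "conservative",
    "params": {"cos_alpha": 0.24},
    "x0": [0.6, 0.13],
    "coords": ["x", "y"],
    "note": "Henon area-preserving quadratic map: rotation by alpha of (x, y - x^2)"
  },
  "arnold_cat": {
    "family": "conservative",
    "params": {},
    "x0": [0.0, 0.7071067811865476],
    "coords": ["x", "y"],
    "note": "x -> x + y mod 1; y -> x + 2 y mod 1"
  },
  "gingerbreadman": {
    "family": "conservative",
    "params": {},
    "x0": [0.5, 3.7],
    "coords": ["x", "y"],
    "note": "x -> 1 - y + |x|; y -> x"
  },
  "web": {
    "family": "conservative",
    "params": {"k": 1.0},
    "x0": [0.0, 3.0],
    "coords": ["x", "y"],
    "note": "chaotic web map with alpha = pi/2: x -> -(y + k sin x); y -> x"
  },
  "lorenz3d": {
    "family": "conservative",
    "params": {},
    "x0": [0.5, 0.5, -1.0],
    "coords": ["x", "y", "z"],
    "note": "Lorenz three-dimensional chaotic map: x -> x y - z; y -> x; z -> y"
  }
}
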