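{
  "version": 1,
  "length_bins": [
    1500,
    3000,
    6000,
    12000,
    24000,
    48000,
    96000
  ],
  "b": [
    [
      3.123594063219967,
      2.789950359260468,
      2.502601828513634,
      2.640757450572486,
      2.4905063330312243,
      2.576980215751697,
      2.576980215751697
    ],
    [
      2.789950359260468,
      2.4782415959931736,
      2.535896217147616,
      2.269087052097246,
      2.1504225610857626,
      2.272162625057986,
      2.272162625057986
    ],
    [
      2.502601828513634,
      2.535896217147616,
      1.9576179736760333,
      2.0610635066257035,
      2.1220805038779353,
      1.9043857695620363,
      1.9043857695620363
    ],
    [
      2.640757450572486,
      2.269087052097246,
      2.0610635066257035,
      1.8825935494512753,
      2.018250243442329,
      1.7245182834292232,
      1.7245182834292232
    ],
    [
      2.4905063330312243,
      2.1504225610857626,
      2.1220805038779353,
      2.018250243442329,
      1.7490790114075299,
      1.6916107661924418,
      1.6916107661924418
    ],
    [
      2.576980215751697,
      2.272162625057986,
      1.9043857695620363,
      1.7245182834292232,
      1.6916107661924418,
      1.695575995925655,
      1.695575995925655
    ],
    [
      2.576980215751697,
      2.272162625057986,
      1.9043857695620363,
      1.7245182834292232,
      1.6916107661924418,
      1.695575995925655,
      1.695575995925655
    ]
  ],
  "c": [
    [
      -67.34774587229712,
      -66.2653766668301,
      -64.77574845282707,
      -66.14544258446527,
      -65.77451544317438,
      -66.70969086011205,
      -66.70969086011205
    ],
    [
      -66.2653766668301,
      -65.77239851920945,
      -66.52530539109334,
      -65.58155204487419,
      -66.41709686403195,
      -66.27472389980394,
      -66.27472389980394
    ],
    [
      -64.77574845282707,
      -66.52530539109334,
      -65.71871844149148,
      -65.99214816212967,
      -66.4573478625695,
      -65.99058629003326,
      -65.99058629003326
    ],
    [
      -66.14544258446527,
      -65.58155204487419,
      -65.99214816212967,
      -66.05399143631205,
      -66.49094727411556,
      -66.23878723979827,
      -66.23878723979827
    ],
    [
      -65.77451544317438,
      -66.41709686403195,
      -66.4573478625695,
      -66.49094727411556,
      -66.15592507898194,
      -66.56550578324057,
      -66.56550578324057
    ],
    [
      -66.70969086011205,
      -66.27472389980394,
      -65.99058629003326,
      -66.23878723979827,
      -66.56550578324057,
      -66.51112780475921,
      -66.51112780475921
    ],
    [
      -66.70969086011205,
      -66.27472389980394,
      -65.99058629003326,
      -66.23878723979827,
      -66.56550578324057,
      -66.51112780475921,
      -66.51112780475921
    ]
  ],
  "fitted": [
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      1,
      1,
      1,
      1,
      1,
      1,
      0
    ],
    [
      0,
      0,
      0,
      0,
      0,
      0,
      0
    ]
  ],
  "prior_ratio": 10.0,
  "eps_log": 1e-300,
  "lambda_floor": 0.01,
  "training_meta": {
    "n_genomes": 12,
    "n_pairs_per_cell": 1200,
    "rng_seed": 20260922,
    "source": "synthetic order-0 Markov genomes (packaged stand-in corpus)",
    "genome_length": 150000,
    "signature_divergence": 0.9
  }
}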