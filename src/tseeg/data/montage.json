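{
 "channels": [
  "FP1",
  "FPZ",
  "FP2",
  "AF3",
  "AF4",
  "F7",
  "F5",
  "F3",
  "F1",
  "FZ",
  "F2",
  "F4",
  "F6",
  "F8",
  "FT7",
  "FC5",
  "FC3",
  "FC1",
  "FCZ",
  "FC2",
  "FC4",
  "FC6",
  "FT8",
  "T7",
  "C5",
  "C3",
  "C1",
  "CZ",
  "C2",
  "C4",
  "C6",
  "T8",
  "TP7",
  "CP5",
  "CP3",
  "CP1",
  "CPZ",
  "CP2",
  "CP4",
  "CP6",
  "TP8",
  "P7",
  "P5",
  "P3",
  "P1",
  "PZ",
  "P2",
  "P4",
  "P6",
  "P8",
  "PO7",
  "PO5",
  "PO3",
  "POZ",
  "PO4",
  "PO6",
  "PO8",
  "CB1",
  "O1",
  "OZ",
  "O2",
  "CB2"
 ],
 "positions": {
  "FP1": [
   -0.3191,
   0.9956
  ],
  "FPZ": [
   -0.003,
   1.0112
  ],
  "FP2": [
   0.3126,
   0.9978
  ],
  "AF3": [
   -0.3157,
   0.7961
  ],
  "AF4": [
   0.3214,
   0.7908
  ],
  "F7": [
   -0.8741,
   0.6388
  ],
  "F5": [
   -0.6578,
   0.5801
  ],
  "F3": [
   -0.4365,
   0.5368
  ],
  "F1": [
   -0.2157,
   0.5112
  ],
  "FZ": [
   -0.0007,
   0.5058
  ],
  "F2": [
   0.2253,
   0.5168
  ],
  "F4": [
   0.4439,
   0.5478
  ],
  "F6": [
   0.6664,
   0.5824
  ],
  "F8": [
   0.8724,
   0.6436
  ],
  "FT7": [
   -1.0415,
   0.2988
  ],
  "FC5": [
   -0.7686,
   0.2754
  ],
  "FC3": [
   -0.5009,
   0.2636
  ],
  "FC1": [
   -0.2459,
   0.251
  ],
  "FCZ": [
   -0.0002,
   0.249
  ],
  "FC2": [
   0.248,
   0.2568
  ],
  "FC4": [
   0.5059,
   0.2688
  ],
  "FC6": [
   0.77,
   0.2832
  ],
  "FT8": [
   1.038,
   0.3134
  ],
  "T7": [
   -1.0664,
   -0.0864
  ],
  "C5": [
   -0.7783,
   -0.0443
  ],
  "C3": [
   -0.5067,
   -0.019
  ],
  "C1": [
   -0.2462,
   -0.0055
  ],
  "CZ": [
   0.0,
   0.0
  ],
  "C2": [
   0.254,
   -0.0031
  ],
  "C4": [
   0.5153,
   -0.0134
  ],
  "C6": [
   0.7842,
   -0.0341
  ],
  "T8": [
   1.0683,
   -0.0738
  ],
  "TP7": [
   -0.9622,
   -0.4161
  ],
  "CP5": [
   -0.7115,
   -0.3325
  ],
  "CP3": [
   -0.4643,
   -0.2747
  ],
  "CP1": [
   -0.2273,
   -0.2413
  ],
  "CPZ": [
   -0.0001,
   -0.2332
  ],
  "CP2": [
   0.2408,
   -0.2403
  ],
  "CP4": [
   0.4761,
   -0.2695
  ],
  "CP6": [
   0.7209,
   -0.3211
  ],
  "TP8": [
   0.9646,
   -0.4121
  ],
  "P7": [
   -0.762,
   -0.6725
  ],
  "P5": [
   -0.5792,
   -0.5745
  ],
  "P3": [
   -0.3887,
   -0.5068
  ],
  "P1": [
   -0.1909,
   -0.4693
  ],
  "PZ": [
   -0.0005,
   -0.4561
  ],
  "P2": [
   0.2042,
   -0.4621
  ],
  "P4": [
   0.3979,
   -0.4996
  ],
  "P6": [
   0.5808,
   -0.5743
  ],
  "P8": [
   0.7634,
   -0.6715
  ],
  "PO7": [
   -0.5211,
   -0.8335
  ],
  "PO5": [
   -0.4132,
   -0.7632
  ],
  "PO3": [
   -0.2879,
   -0.7152
  ],
  "POZ": [
   -0.0014,
   -0.6828
  ],
  "PO4": [
   0.2858,
   -0.7203
  ],
  "PO6": [
   0.4166,
   -0.761
  ],
  "PO8": [
   0.521,
   -0.834
  ],
  "CB1": [
   -0.2989,
   -1.0355
  ],
  "O1": [
   -0.2629,
   -0.9106
  ],
  "OZ": [
   -0.0025,
   -0.9123
  ],
  "O2": [
   0.2605,
   -0.9113
  ],
  "CB2": [
   0.2963,
   -1.0363
  ]
 },
 "regions": {
  "left_hemisphere": [
   "FP1",
   "AF3",
   "F7",
   "F5",
   "F3",
   "F1",
   "FT7",
   "FC5",
   "FC3",
   "FC1",
   "T7",
   "C5",
   "C3",
   "C1",
   "TP7",
   "CP5",
   "CP3",
   "CP1",
   "P7",
   "P5",
   "P3",
   "P1",
   "PO7",
   "PO5",
   "PO3",
   "CB1",
   "O1"
  ],
  "right_hemisphere": [
   "FP2",
   "AF4",
   "F2",
   "F4",
   "F6",
   "F8",
   "FC2",
   "FC4",
   "FC6",
   "FT8",
   "C2",
   "C4",
   "C6",
   "T8",
   "CP2",
   "CP4",
   "CP6",
   "TP8",
   "P2",
   "P4",
   "P6",
   "P8",
   "PO4",
   "PO6",
   "PO8",
   "O2",
   "CB2"
  ],
  "anterior": [
   "FP1",
   "FPZ",
   "FP2",
   "AF3",
   "AF4",
   "F7",
   "F5",
   "F3",
   "F1",
   "FZ",
   "F2",
   "F4",
   "F6",
   "F8",
   "FT7",
   "FC5",
   "FC3",
   "FC1",
   "FCZ",
   "FC2",
   "FC4",
   "FC6",
   "FT8"
  ],
  "posterior": [
   "TP7",
   "CP5",
   "CP3",
   "CP1",
   "CPZ",
   "CP2",
   "CP4",
   "CP6",
   "TP8",
   "P7",
   "P5",
   "P3",
   "P1",
   "PZ",
   "P2",
   "P4",
   "P6",
   "P8",
   "PO7",
   "PO5",
   "PO3",
   "POZ",
   "PO4",
   "PO6",
   "PO8",
   "CB1",
   "O1",
   "OZ",
   "O2",
   "CB2"
  ],
  "left_anterior": [
   "FP1",
   "AF3",
   "F7",
   "F5",
   "F3",
   "F1",
   "FT7",
   "FC5",
   "FC3",
   "FC1"
  ],
  "right_anterior": [
   "FP2",
   "AF4",
   "F2",
   "F4",
   "F6",
   "F8",
   "FC2",
   "FC4",
   "FC6",
   "FT8"
  ],
  "left_posterior": [
   "TP7",
   "CP5",
   "CP3",
   "CP1",
   "P7",
   "P5",
   "P3",
   "P1",
   "PO7",
   "PO5",
   "PO3",
   "CB1",
   "O1"
  ],
  "right_posterior": [
   "CP2",
   "CP4",
   "CP6",
   "TP8",
   "P2",
   "P4",
   "P6",
   "P8",
   "PO4",
   "PO6",
   "PO8",
   "O2",
   "CB2"
  ]
 },
 "boundary": {
  "midline": [
   "FPZ",
   "FZ",
   "FCZ",
   "CZ",
   "CPZ",
   "PZ",
   "POZ",
   "OZ"
  ],
  "central_row": [
   "T7",
   "C5",
   "C3",
   "C1",
   "CZ",
   "C2",
   "C4",
   "C6",
   "T8"
  ]
 }
}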