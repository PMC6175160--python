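! 3-21G split-valence basis (H, C, N, O), Gaussian94 text format.
****
H     0
S    2   1.00
      5.44717800             0.15628500
      0.82454700             0.90469100
S    1   1.00
      0.18319200             1.00000000
****
C     0
S    3   1.00
    172.25600000             0.06176690
     25.91090000             0.35879400
      5.53335000             0.70071300
SP   2   1.00
      3.66498000            -0.39589700             0.23646000
      0.77054500             1.21584000             0.86061900
SP   1   1.00
      0.19585700             1.00000000             1.00000000
****
N     0
S    3   1.00
    242.76600000             0.05986570
     36.48510000             0.35295500
      7.81449000             0.70651300
SP   2   1.00
      5.42522000            -0.41330100             0.23797200
      1.14915000             1.22442000             0.85895300
SP   1   1.00
      0.28320500             1.00000000             1.00000000
****
O     0
S    3   1.00
    322.03700000             0.05923940
     48.43080000             0.35150000
     10.42060000             0.70765800
SP   2   1.00
      7.40294000            -0.40445300             0.24458600
      1.57620000             1.22156000             0.85395500
SP   1   1.00
      0.37368400             1.00000000             1.00000000
****
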