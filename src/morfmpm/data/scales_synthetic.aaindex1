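H CIDH920101
D SYNTHETIC stand-in values, hydrophobicity (alpha-protein normalized) theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.283  -1.136  -0.994  -0.730   1.283  -0.769  -0.898  -0.009  -0.813   2.078
   1.680  -1.364   1.040   1.009  -0.256  -0.048  -0.489   1.604  -0.240  -0.170
//
H EISD860103
D SYNTHETIC stand-in values, solvation free energy theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.462  -1.066  -0.932  -1.036   0.927  -0.915  -1.015  -0.292  -1.282   2.006
   1.572  -1.022   0.806   1.052  -0.409  -0.327  -0.572   1.672   0.028  -0.679
//
H NISK860101
D SYNTHETIC stand-in values, inter-residue contact energy theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.528   1.178   0.985   1.095  -1.398   1.021   0.987  -0.658   0.340  -1.629
  -1.691   1.034  -0.708  -0.731   0.033   0.413   0.453  -1.451   0.026   0.021
//
H QIAN880105
D SYNTHETIC stand-in values, helix propensity (neural-network weight) theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.630  -0.261  -1.260   0.439  -1.252   0.650   1.722  -1.826  -0.104   0.185
   0.693   0.172   1.481   0.557  -1.206  -0.029  -0.910   0.206  -0.979  -0.653
//
H ROBB760101
D SYNTHETIC stand-in values, helix information measure theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.712  -0.223  -1.025  -0.285  -1.628   0.505   1.951  -1.620  -0.122   0.178
   1.017   0.507   1.167   0.559  -1.865   0.702  -1.258   0.120  -0.613  -0.563
//
H ROBB760108
D SYNTHETIC stand-in values, turn information measure theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.435   0.084   0.059   0.366  -1.283   1.513   1.875   1.220   0.156  -1.501
  -1.673   1.191  -0.193  -1.437   1.330  -1.230  -1.255  -0.875   1.068   0.430
//
H ROBB760112
D SYNTHETIC stand-in values, coil information measure theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.604   0.398   0.331   0.821  -0.988   1.134   1.578   0.186   0.481  -1.211
  -0.673   0.647  -1.012  -1.629   1.826  -1.540  -1.846  -0.953   1.281   0.449
//
H ROBB760113
D SYNTHETIC stand-in values, loop information measure theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.102   0.227  -0.330   0.632  -1.128   0.466   1.402   0.284   0.040  -0.789
  -0.832   0.758  -0.090  -1.410   1.086  -1.295  -1.101  -1.071   0.405   0.002
//
H CORJ870103
D SYNTHETIC stand-in values, hydrophobicity scanning profile A theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.230  -1.461  -0.875  -1.086   0.501  -0.799  -1.032  -0.122  -1.215   1.794
   1.499  -1.009   0.734   1.086  -0.285   0.025   0.248   1.766  -0.225   0.459
//
H CORJ870106
D SYNTHETIC stand-in values, hydrophobicity scanning profile B theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.127  -1.283  -0.688  -1.160   0.845  -0.222  -1.484  -0.249  -0.843   1.250
   1.466  -1.342   0.413   1.141  -1.087   0.067   0.334   1.690  -0.545   0.120
//
H CORJ870107
D SYNTHETIC stand-in values, hydrophobicity scanning profile C theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.057  -1.065  -0.304  -1.139   1.165  -0.698  -1.668   0.072  -0.653   1.083
   0.411  -1.093  -0.017   0.703  -1.255   0.635   0.687   2.004  -0.701  -0.062
//
H CORJ870108
D SYNTHETIC stand-in values, hydrophobicity scanning profile D theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.518  -0.233  -0.756  -0.829   0.085  -0.080  -1.623  -0.261  -0.296   1.987
   1.214  -0.980   0.849   0.960  -0.847  -0.248   0.846   1.385  -0.668   0.073
//
H MIYS990104
D SYNTHETIC stand-in values, pairwise contact energy (relative) theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.803   1.885   0.974   1.264  -0.921   0.858   1.479  -0.136   0.950  -2.124
  -1.523   1.159  -0.994  -1.353   0.597   0.125   0.240  -1.705   0.479   0.285
//
H GLOB_R465
D SYNTHETIC stand-in values, Remark-465-style disorder propensity theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.834   0.505   0.408   0.652  -1.132   1.226   1.145   0.848   0.072  -0.603
  -0.783   0.799   0.009  -1.339   1.467  -1.983  -1.653  -1.035   0.976   0.054
//
H GLOB_DLRX
D SYNTHETIC stand-in values, Deleage/Roux-style coil minus helix propensity theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.023   0.444   0.872   0.468  -0.009   0.520   0.443   0.998  -0.152  -0.589
  -0.604   0.772  -0.816  -1.045   1.744  -1.304  -0.069  -0.744   1.114   0.446
//
H GLOB_BF2S
D SYNTHETIC stand-in values, B-factor(2STD)-style flexibility propensity theme (not the published scale)
R morfmpm vendored registry
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.427   0.141   0.123   0.333  -0.806   0.686   0.516   0.199  -0.021  -0.197
  -0.648   0.447  -0.283  -0.589   1.057  -1.236  -1.188   0.181   0.931   0.617
//
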