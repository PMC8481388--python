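ATOM      1  N   ALA A   1       0.271  -1.524  -0.918  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.368  -1.818  -0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.492  -0.739   1.063  1.00  0.00           C
ATOM      4  O   ALA A   1       1.615  -1.036   2.251  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.167  -3.186   0.655  1.00  0.00           C
ATOM      6  N   ALA A   2       1.459   0.518   0.631  1.00  0.00           N
ATOM      7  CA  ALA A   2       1.568   1.648   1.549  1.00  0.00           C
ATOM      8  C   ALA A   2       0.483   1.593   2.612  1.00  0.00           C
ATOM      9  O   ALA A   2       0.756   1.763   3.799  1.00  0.00           O
ATOM     10  CB  ALA A   2       2.950   1.675   2.204  1.00  0.00           C
ATOM     11  N   ALA A   3      -0.751   1.354   2.180  1.00  0.00           N
ATOM     12  CA  ALA A   3      -1.884   1.275   3.098  1.00  0.00           C
ATOM     13  C   ALA A   3      -1.651   0.215   4.161  1.00  0.00           C
ATOM     14  O   ALA A   3      -1.864   0.456   5.348  1.00  0.00           O
ATOM     15  CB  ALA A   3      -2.138   2.634   3.753  1.00  0.00           C
ATOM     16  N   ALA A   4      -1.212  -0.964   3.729  1.00  0.00           N
ATOM     17  CA  ALA A   4      -0.948  -2.068   4.646  1.00  0.00           C
ATOM     18  C   ALA A   4       0.060  -1.664   5.710  1.00  0.00           C
ATOM     19  O   ALA A   4      -0.143  -1.913   6.897  1.00  0.00           O
ATOM     20  CB  ALA A   4      -2.247  -2.542   5.302  1.00  0.00           C
ATOM     21  N   ALA A   5       1.150  -1.036   5.277  1.00  0.00           N
ATOM     22  CA  ALA A   5       2.196  -0.594   6.195  1.00  0.00           C
ATOM     23  C   ALA A   5       1.631   0.333   7.259  1.00  0.00           C
ATOM     24  O   ALA A   5       1.911   0.174   8.446  1.00  0.00           O
ATOM     25  CB  ALA A   5       2.877  -1.798   6.851  1.00  0.00           C
ATOM     26  N   ALA A   6       0.833   1.305   6.826  1.00  0.00           N
ATOM     27  CA  ALA A   6       0.225   2.264   7.744  1.00  0.00           C
ATOM     28  C   ALA A   6      -0.597   1.554   8.807  1.00  0.00           C
ATOM     29  O   ALA A   6      -0.486   1.856   9.995  1.00  0.00           O
ATOM     30  CB  ALA A   6       1.299   3.134   8.399  1.00  0.00           C
ATOM     31  N   ALA A   7      -1.424   0.607   8.375  1.00  0.00           N
ATOM     32  CA  ALA A   7      -2.270  -0.151   9.293  1.00  0.00           C
ATOM     33  C   ALA A   7      -1.435  -0.845  10.356  1.00  0.00           C
ATOM     34  O   ALA A   7      -1.750  -0.785  11.543  1.00  0.00           O
ATOM     35  CB  ALA A   7      -3.305   0.766   9.948  1.00  0.00           C
ATOM     36  N   ALA A   8      -0.364  -1.505   9.924  1.00  0.00           N
ATOM     37  CA  ALA A   8       0.522  -2.214  10.842  1.00  0.00           C
ATOM     38  C   ALA A   8       1.069  -1.276  11.905  1.00  0.00           C
ATOM     39  O   ALA A   8       1.062  -1.597  13.092  1.00  0.00           O
ATOM     40  CB  ALA A   8      -0.212  -3.386  11.497  1.00  0.00           C
ATOM     41  N   ALA A   9       1.544  -0.112  11.472  1.00  0.00           N
ATOM     42  CA  ALA A   9       2.098   0.880  12.390  1.00  0.00           C
ATOM     43  C   ALA A   9       1.083   1.265  13.454  1.00  0.00           C
ATOM     44  O   ALA A   9       1.401   1.311  14.641  1.00  0.00           O
ATOM     45  CB  ALA A   9       3.375   0.349  13.046  1.00  0.00           C
ATOM     46  N   ALA A  10      -0.144   1.542  13.021  1.00  0.00           N
ATOM     47  CA  ALA A  10      -1.213   1.925  13.939  1.00  0.00           C
ATOM     48  C   ALA A  10      -1.426   0.860  15.003  1.00  0.00           C
ATOM     49  O   ALA A  10      -1.523   1.166  16.190  1.00  0.00           O
ATOM     50  CB  ALA A  10      -0.899   3.271  14.594  1.00  0.00           C
ATOM     51  N   ALA A  11      -1.497  -0.396  14.570  1.00  0.00           N
ATOM     52  CA  ALA A  11      -1.699  -1.513  15.488  1.00  0.00           C
ATOM     53  C   ALA A  11      -0.613  -1.548  16.551  1.00  0.00           C
ATOM     54  O   ALA A  11      -0.899  -1.695  17.739  1.00  0.00           O
ATOM     55  CB  ALA A  11      -3.079  -1.425  16.143  1.00  0.00           C
ATOM     56  N   ALA A  12       0.637  -1.411  16.119  1.00  0.00           N
ATOM     57  CA  ALA A  12       1.772  -1.427  17.037  1.00  0.00           C
ATOM     58  C   ALA A  12       1.628  -0.350  18.100  1.00  0.00           C
ATOM     59  O   ALA A  12       1.820  -0.608  19.287  1.00  0.00           O
ATOM     60  CB  ALA A  12       1.913  -2.802  17.692  1.00  0.00           C
ATOM     61  N   ALA A  13       1.287   0.860  17.668  1.00  0.00           N
ATOM     62  CA  ALA A  13       1.116   1.983  18.585  1.00  0.00           C
ATOM     63  C   ALA A  13       0.078   1.663  19.649  1.00  0.00           C
ATOM     64  O   ALA A  13       0.300   1.895  20.836  1.00  0.00           O
ATOM     65  CB  ALA A  13       2.449   2.348  19.241  1.00  0.00           C
ATOM     66  N   ALA A  14      -1.061   1.128  19.216  1.00  0.00           N
ATOM     67  CA  ALA A  14      -2.139   0.774  20.134  1.00  0.00           C
ATOM     68  C   ALA A  14      -1.653  -0.197  21.198  1.00  0.00           C
ATOM     69  O   ALA A  14      -1.918  -0.016  22.385  1.00  0.00           O
ATOM     70  CB  ALA A  14      -2.719   2.029  20.790  1.00  0.00           C
ATOM     71  N   ALA A  15      -0.938  -1.232  20.765  1.00  0.00           N
ATOM     72  CA  ALA A  15      -0.411  -2.238  21.683  1.00  0.00           C
ATOM     73  C   ALA A  15       0.466  -1.598  22.746  1.00  0.00           C
ATOM     74  O   ALA A  15       0.331  -1.890  23.934  1.00  0.00           O
ATOM     75  CB  ALA A  15      -1.554  -3.016  22.338  1.00  0.00           C
ATOM     76  N   ALA A  16       1.369  -0.723  22.314  1.00  0.00           N
ATOM     77  CA  ALA A  16       2.275  -0.038  23.232  1.00  0.00           C
ATOM     78  C   ALA A  16       1.500   0.723  24.295  1.00  0.00           C
ATOM     79  O   ALA A  16       1.809   0.638  25.482  1.00  0.00           O
ATOM     80  CB  ALA A  16       3.230  -1.037  23.887  1.00  0.00           C
ATOM     81  N   ALA A  17       0.487   1.470  23.863  1.00  0.00           N
ATOM     82  CA  ALA A  17      -0.337   2.250  24.781  1.00  0.00           C
ATOM     83  C   ALA A  17      -0.960   1.360  25.844  1.00  0.00           C
ATOM     84  O   ALA A  17      -0.927   1.680  27.031  1.00  0.00           O
ATOM     85  CB  ALA A  17       0.491   3.357  25.436  1.00  0.00           C
ATOM     86  N   ALA A  18      -1.530   0.239  25.412  1.00  0.00           N
ATOM     87  CA  ALA A  18      -2.164  -0.703  26.329  1.00  0.00           C
ATOM     88  C   ALA A  18      -1.184  -1.171  27.393  1.00  0.00           C
ATOM     89  O   ALA A  18      -1.504  -1.191  28.580  1.00  0.00           O
ATOM     90  CB  ALA A  18      -3.392  -0.068  26.985  1.00  0.00           C
ATOM     91  N   ALA A  19       0.016  -1.548  26.960  1.00  0.00           N
ATOM     92  CA  ALA A  19       1.050  -2.019  27.878  1.00  0.00           C
ATOM     93  C   ALA A  19       1.350  -0.975  28.942  1.00  0.00           C
ATOM     94  O   ALA A  19       1.422  -1.288  30.129  1.00  0.00           O
ATOM     95  CB  ALA A  19       0.626  -3.334  28.534  1.00  0.00           C
ATOM     96  N   ALA A  20       1.524   0.271  28.509  1.00  0.00           N
ATOM     97  CA  ALA A  20       1.818   1.368  29.427  1.00  0.00           C
ATOM     98  C   ALA A  20       0.739   1.492  30.490  1.00  0.00           C
ATOM     99  O   ALA A  20       1.036   1.614  31.678  1.00  0.00           O
ATOM    100  CB  ALA A  20       3.186   1.166  30.082  1.00  0.00           C
TER     101      ALA A  20
END
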