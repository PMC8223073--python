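age,ow_cut,ob_cut
6.0,17.55,19.78
6.5,17.71,20.23
7.0,17.92,20.63
7.5,18.16,21.09
8.0,18.44,21.60
8.5,18.76,22.17
9.0,19.10,22.77
9.5,19.46,23.39
10.0,19.84,24.00
10.5,20.20,24.57
11.0,20.55,25.10
11.5,20.89,25.58
12.0,21.22,26.02
12.5,21.56,26.43
13.0,21.91,26.84
13.5,22.27,27.25
14.0,22.62,27.63
14.5,22.96,27.98
15.0,23.29,28.30
15.5,23.60,28.60
16.0,23.90,28.88
16.5,24.19,29.14
17.0,24.46,29.41
17.5,24.73,29.70
18.0,25.00,30.00
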