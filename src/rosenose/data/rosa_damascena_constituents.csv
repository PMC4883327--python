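constituent,g1,g2,g3,g4,g5,g6,g7,g8,g9,g10
Phenyl ethyl alcohol,-,-,-,0.21,0.3,0.3,0.37,0.61,0.18,0.64
Trans rose oxide,0.4,0.18,0.32,0.12,0.23,0.4,0.61,0.5,0.61,1.25
Citronellol,1.25,0.48,4.73,2.14,8.48,13.35,24.1,33.7,53.1,28.18
Nerol,-,-,-,-,0.6,0.1,0.1,3.56,2.01,16.2
Geraniol,0.5,3.25,2.66,6.33,6.15,7.25,12.1,26.05,15.16,30.02
Geranial,-,0.15,0.14,0.1,0.2,0.21,0.1,0.27,0.26,0.48
alpha-Eudesmol,1.73,2.86,2.35,-,2.18,3.15,-,0.61,-,0.72
beta-Eudesmol,1.9,4.33,2.77,2.01,2.52,2.84,-,0.67,-,-
gamma-Eudesmol,1.48,1.77,1.4,-,2.43,2.68,-,0.57,-,-
Cyclohexanemethanol,0.44,0.62,0.17,-,0.53,1.25,-,-,-,-
Dioctyl phthalate,15.9,-,-,-,-,-,-,-,-,-
Farnesol,-,0.95,0.9,-,-,-,1.53,0.27,-,-
Octyl phthalate,-,12.0,-,3.91,0.22,-,-,0.28,-,2.48
Geranyl acetate,-,-,0.1,0.5,-,0.71,1.24,1.12,0.44,2.05
Methyleugenol,-,-,0.15,-,-,-,0.75,0.25,0.28,-
Diisooctyl phthalate,-,-,4.88,-,-,-,-,-,5.16,-
Linalool,-,-,-,0.83,-,-,0.31,0.53,-,-
Neral,0.1,0.23,0.34,0.66,0.7,0.78,0.9,0.94,1.0,1.3
3-Methyl-4-isopropylphenol,-,-,-,-,-,-,0.3,-,0.53,-
Eugenol,-,-,-,-,-,-,0.4,-,-,-
Apilo,-,-,-,-,-,-,0.42,0.23,-,-
Nonacosane,-,-,-,-,-,-,0.56,0.37,-,-
Nonanal,-,-,-,-,-,-,-,0.13,-,-
Anethole,-,-,-,-,-,-,-,0.5,0.55,-
Chavibetol,-,-,-,-,-,-,-,0.28,0.22,-
Docosane,-,0.55,5.0,6.51,4.83,4.05,0.53,4.0,3.82,-
Pentacosane,-,2.44,-,-,-,1.65,2.06,-,2.25,-
z-5-Nonadecene,5.6,5.35,6.35,6.33,6.35,-,-,-,2.93,-
Nonadecane,33.1,30.5,33.7,37.2,40.3,35.9,17.6,14.2,12.76,10.94
Eicosane,3.28,3.43,5.4,4.15,3.76,2.73,3.12,2.28,2.48,1.9
Hexadecane,4.48,-,-,-,-,-,-,-,-,-
1-Tetradecene,-,-,0.13,-,-,-,-,-,-,-
9-Eicosene,-,-,0.18,-,-,-,-,0.2,-,-
9-Nonadecene,-,-,0.37,0.35,-,-,-,0.33,0.21,-
cis-9-Tricosene,-,-,0.28,-,-,-,0.55,-,0.46,-
Bicyclo[10.8.0]eicosane-cis,0.13,-,-,-,-,-,-,-,-,-
Hexacosane,-,-,0.2,-,0.2,-,-,-,-,-
Octacosane,-,-,0.07,-,-,-,-,0.09,-,-
Heneicosane,20.0,20.2,19.6,25.7,20.7,17.34,11.6,11.2,9.66,10.0
Tetracosane,2.87,3.68,0.6,0.27,2.42,-,0.41,0.33,2.6,0.5
Neopentylidenecyclohexane,-,-,-,-,1.35,-,-,-,-,-
"1,21-Docosadiene",-,-,-,-,0.15,-,-,-,-,-
1-Octadecene,-,-,-,-,-,6.03,-,-,-,-
8-Heptadecan,0.52,0.86,1.16,-,1.84,1.5,-,0.35,-,-
"2,6-Octadiene, 2,6-dimethyl",-,-,-,-,-,-,0.35,0.37,0.36,-
Heptacosane,2.91,-,2.66,3.37,0.07,2.0,2.13,2.4,0.24,-
Bergamoten,-,-,-,-,-,-,0.84,-,-,-
Teriacontane,0.31,-,-,-,-,-,-,-,0.4,1.78
1-Nonadecane,-,-,-,-,-,-,3.5,-,-,-
Tricosane,-,-,-,-,-,-,3.75,-,-,-
"1,19-Eicosadiene",-,-,-,-,-,-,-,0.16,-,-
"5-Eicosene, (E)",-,-,-,-,-,-,-,-,-,3.96
Pentadecane,0.36,-,0.4,-,-,0.28,-,0.21,0.21,-
Heptadecane,2.93,2.17,3,2.51,3.67,2.1,1.56,1.78,1.6,-
7-Tetradecyne,0.4,-,-,-,-,-,-,-,-,-
Octadecane,0.25,5.0,0.27,2.68,0.4,-,0.4,2.16,0.6,-
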