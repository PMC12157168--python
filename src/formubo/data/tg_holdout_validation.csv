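formulation,experimental_tg,linear_predicted_tg,xgboost_predicted_tg
1,-36.0,-38.7,-35.7
2,-34.1,-37.0,-34.0
3,-36.7,-41.3,-35.7
4,-34.6,-40.0,-34.0
5,-34.5,-38.7,-33.0
6,-32.9,-36.3,-32.8
7,-34.8,-35.3,-34.9
8,-34.3,-34.7,-34.3
9,-31.4,-37.3,-31.3
10,-30.5,-32.7,-31.5
11,-36.5,-36.7,-35.9
12,-34.1,-37.0,-34.0
13,-34.9,-34.1,-33.0
14,-32.3,-35.4,-32.3
15,-34.7,-39.9,-34.6
16,-35.6,-37.9,-34.1
17,-31.8,-33.1,-32.4
18,-32.6,-34.0,-32.9
19,-34.7,-35.1,-34.3
20,-33.5,-34.3,-33.1
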