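# Synthetic stand-in for the published 109-gene non-epithelial residual metastatic signature.
# The original supplementary gene list is not redistributable; these are
# generated placeholder symbols preserving only the cardinality (109).
TME-SIG-001
TME-SIG-002
TME-SIG-003
TME-SIG-004
TME-SIG-005
TME-SIG-006
TME-SIG-007
TME-SIG-008
TME-SIG-009
TME-SIG-010
TME-SIG-011
TME-SIG-012
TME-SIG-013
TME-SIG-014
TME-SIG-015
TME-SIG-016
TME-SIG-017
TME-SIG-018
TME-SIG-019
TME-SIG-020
TME-SIG-021
TME-SIG-022
TME-SIG-023
TME-SIG-024
TME-SIG-025
TME-SIG-026
TME-SIG-027
TME-SIG-028
TME-SIG-029
TME-SIG-030
TME-SIG-031
TME-SIG-032
TME-SIG-033
TME-SIG-034
TME-SIG-035
TME-SIG-036
TME-SIG-037
TME-SIG-038
TME-SIG-039
TME-SIG-040
TME-SIG-041
TME-SIG-042
TME-SIG-043
TME-SIG-044
TME-SIG-045
TME-SIG-046
TME-SIG-047
TME-SIG-048
TME-SIG-049
TME-SIG-050
TME-SIG-051
TME-SIG-052
TME-SIG-053
TME-SIG-054
TME-SIG-055
TME-SIG-056
TME-SIG-057
TME-SIG-058
TME-SIG-059
TME-SIG-060
TME-SIG-061
TME-SIG-062
TME-SIG-063
TME-SIG-064
TME-SIG-065
TME-SIG-066
TME-SIG-067
TME-SIG-068
TME-SIG-069
TME-SIG-070
TME-SIG-071
TME-SIG-072
TME-SIG-073
TME-SIG-074
TME-SIG-075
TME-SIG-076
TME-SIG-077
TME-SIG-078
TME-SIG-079
TME-SIG-080
TME-SIG-081
TME-SIG-082
TME-SIG-083
TME-SIG-084
TME-SIG-085
TME-SIG-086
TME-SIG-087
TME-SIG-088
TME-SIG-089
TME-SIG-090
TME-SIG-091
TME-SIG-092
TME-SIG-093
TME-SIG-094
TME-SIG-095
TME-SIG-096
TME-SIG-097
TME-SIG-098
TME-SIG-099
TME-SIG-100
TME-SIG-101
TME-SIG-102
TME-SIG-103
TME-SIG-104
TME-SIG-105
TME-SIG-106
TME-SIG-107
TME-SIG-108
TME-SIG-109
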