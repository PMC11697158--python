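# Synthetic stand-in for the published 177-gene epithelial-refined metastatic signature.
# The original supplementary gene list is not redistributable; these are
# generated placeholder symbols preserving only the cardinality (177).
EPI-SIG-001
EPI-SIG-002
EPI-SIG-003
EPI-SIG-004
EPI-SIG-005
EPI-SIG-006
EPI-SIG-007
EPI-SIG-008
EPI-SIG-009
EPI-SIG-010
EPI-SIG-011
EPI-SIG-012
EPI-SIG-013
EPI-SIG-014
EPI-SIG-015
EPI-SIG-016
EPI-SIG-017
EPI-SIG-018
EPI-SIG-019
EPI-SIG-020
EPI-SIG-021
EPI-SIG-022
EPI-SIG-023
EPI-SIG-024
EPI-SIG-025
EPI-SIG-026
EPI-SIG-027
EPI-SIG-028
EPI-SIG-029
EPI-SIG-030
EPI-SIG-031
EPI-SIG-032
EPI-SIG-033
EPI-SIG-034
EPI-SIG-035
EPI-SIG-036
EPI-SIG-037
EPI-SIG-038
EPI-SIG-039
EPI-SIG-040
EPI-SIG-041
EPI-SIG-042
EPI-SIG-043
EPI-SIG-044
EPI-SIG-045
EPI-SIG-046
EPI-SIG-047
EPI-SIG-048
EPI-SIG-049
EPI-SIG-050
EPI-SIG-051
EPI-SIG-052
EPI-SIG-053
EPI-SIG-054
EPI-SIG-055
EPI-SIG-056
EPI-SIG-057
EPI-SIG-058
EPI-SIG-059
EPI-SIG-060
EPI-SIG-061
EPI-SIG-062
EPI-SIG-063
EPI-SIG-064
EPI-SIG-065
EPI-SIG-066
EPI-SIG-067
EPI-SIG-068
EPI-SIG-069
EPI-SIG-070
EPI-SIG-071
EPI-SIG-072
EPI-SIG-073
EPI-SIG-074
EPI-SIG-075
EPI-SIG-076
EPI-SIG-077
EPI-SIG-078
EPI-SIG-079
EPI-SIG-080
EPI-SIG-081
EPI-SIG-082
EPI-SIG-083
EPI-SIG-084
EPI-SIG-085
EPI-SIG-086
EPI-SIG-087
EPI-SIG-088
EPI-SIG-089
EPI-SIG-090
EPI-SIG-091
EPI-SIG-092
EPI-SIG-093
EPI-SIG-094
EPI-SIG-095
EPI-SIG-096
EPI-SIG-097
EPI-SIG-098
EPI-SIG-099
EPI-SIG-100
EPI-SIG-101
EPI-SIG-102
EPI-SIG-103
EPI-SIG-104
EPI-SIG-105
EPI-SIG-106
EPI-SIG-107
EPI-SIG-108
EPI-SIG-109
EPI-SIG-110
EPI-SIG-111
EPI-SIG-112
EPI-SIG-113
EPI-SIG-114
EPI-SIG-115
EPI-SIG-116
EPI-SIG-117
EPI-SIG-118
EPI-SIG-119
EPI-SIG-120
EPI-SIG-121
EPI-SIG-122
EPI-SIG-123
EPI-SIG-124
EPI-SIG-125
EPI-SIG-126
EPI-SIG-127
EPI-SIG-128
EPI-SIG-129
EPI-SIG-130
EPI-SIG-131
EPI-SIG-132
EPI-SIG-133
EPI-SIG-134
EPI-SIG-135
EPI-SIG-136
EPI-SIG-137
EPI-SIG-138
EPI-SIG-139
EPI-SIG-140
EPI-SIG-141
EPI-SIG-142
EPI-SIG-143
EPI-SIG-144
EPI-SIG-145
EPI-SIG-146
EPI-SIG-147
EPI-SIG-148
EPI-SIG-149
EPI-SIG-150
EPI-SIG-151
EPI-SIG-152
EPI-SIG-153
EPI-SIG-154
EPI-SIG-155
EPI-SIG-156
EPI-SIG-157
EPI-SIG-158
EPI-SIG-159
EPI-SIG-160
EPI-SIG-161
EPI-SIG-162
EPI-SIG-163
EPI-SIG-164
EPI-SIG-165
EPI-SIG-166
EPI-SIG-167
EPI-SIG-168
EPI-SIG-169
EPI-SIG-170
EPI-SIG-171
EPI-SIG-172
EPI-SIG-173
EPI-SIG-174
EPI-SIG-175
EPI-SIG-176
EPI-SIG-177
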